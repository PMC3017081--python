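"""Topological descriptors for nodes and node sets.

Implements the five descriptors commonly used to profile protein sets on an
interaction network -- degree, local clustering coefficient, (unnormalised)
betweenness centrality, eigenvector centrality and shortest path length --
plus summaries over node sets and matched-size random baselines.

Conventions:

* betweenness is the raw sum of shortest-path fractions over unordered node
  pairs, endpoints excluded, unnormalised;
* eigenvector centrality is computed per connected component and Euclidean-
  normalised within each component (power iteration, tol 1e-8, <=1000 steps);
* the mean shortest path of a node set averages over connected in-set pairs
  only.  This differs deliberately from the penalised distance used inside the
  extension compactness score: a descriptive statistic should not be dominated
  by a penalty constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "TopologySummary",
    "RandomSetBaseline",
    "node_degree",
    "clustering_coefficient",
    "betweenness",
    "eigenvector_centrality",
    "shortest_path_lengths",
    "topology_summary",
    "random_matched_baseline",
]

_DESCRIPTORS = (
    "mean_degree",
    "mean_clustering",
    "mean_betweenness",
    "mean_eigenvector",
    "mean_shortest_path",
)


@dataclass(frozen=True)
class TopologySummary:
    """Per-descriptor means over a node set."""

    mean_degree: float
    mean_clustering: float
    mean_betweenness: float
    mean_eigenvector: float
    mean_shortest_path: float  # NaN when no connected in-set pair exists


@dataclass(frozen=True)
class RandomSetBaseline:
    """Mean/std of each descriptor across uniform random matched-size sets."""

    n_sets: int
    size: int
    seed: int
    means: Mapping[str, float]
    stds: Mapping[str, float]


def _require_node(network: nx.Graph, v: str) -> None:
    if not network.has_node(v):
        raise KeyError(f"node {v!r} not in network")


def node_degree(network: nx.Graph, v: str) -> int:
    _require_node(network, v)
    return network.degree(v)


def clustering_coefficient(network: nx.Graph, v: str) -> float:
    """Fraction of realised edges among the neighbours of ``v`` (0 if deg < 2)."""
    _require_node(network, v)
    return float(nx.clustering(network, v))


def betweenness(network: nx.Graph, v: str) -> float:
    _require_node(network, v)
    return betweenness_all(network)[v]


def betweenness_all(network: nx.Graph) -> dict[str, float]:
    """Unnormalised betweenness for every node (endpoints excluded)."""
    return dict(nx.betweenness_centrality(network, normalized=False))


def eigenvector_centrality(network: nx.Graph) -> dict[str, float]:
    """Principal-eigenvector scores, per connected component.

    Each component's score vector is non-negative with unit Euclidean norm.
    Single-node components get score 1.0.  Raises on non-convergence, naming
    a node of the offending component.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("eigenvector centrality undefined on an empty network")
    scores: dict[str, float] = {}
    for component in nx.connected_components(network):
        if len(component) == 1:
            scores[next(iter(component))] = 1.0
            continue
        sub = network.subgraph(component)
        try:
            comp_scores = nx.eigenvector_centrality(sub, max_iter=1000, tol=1e-8)
        except nx.PowerIterationFailedConvergence as exc:
            raise RuntimeError(
                "eigenvector centrality did not converge on the component "
                f"containing {next(iter(component))!r}"
            ) from exc
        # networkx normalises to unit Euclidean norm already; renormalise to be safe
        norm = float(np.hypot.reduce(np.fromiter(comp_scores.values(), float)))
        scores.update({n: s / norm for n, s in comp_scores.items()})
    return scores


def shortest_path_lengths(
    network: nx.Graph, sources: Iterable[str]
) -> dict[tuple[str, str], int]:
    """BFS distances from each source to every reachable node.

    Unreachable pairs are absent from the result.  The (source, source)
    distance 0 is included.
    """
    sources = list(sources)
    for s in sources:
        _require_node(network, s)
    out: dict[tuple[str, str], int] = {}
    for s in sources:
        for t, d in nx.single_source_shortest_path_length(network, s).items():
            out[(s, t)] = d
    return out


def mean_within_set_distance(network: nx.Graph, node_set: Iterable[str]) -> float:
    """Mean shortest-path length over connected unordered in-set pairs (NaN if none)."""
    nodes = sorted(set(node_set))
    total = 0
    n_pairs = 0
    for i, s in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(network, s)
        for t in nodes[i + 1 :]:
            if t in dist:
                total += dist[t]
                n_pairs += 1
    return total / n_pairs if n_pairs else float("nan")


def topology_summary(network: nx.Graph, node_set: Iterable[str]) -> TopologySummary:
    """Descriptor means over a non-empty node set."""
    nodes = sorted(set(node_set))
    if not nodes:
        raise ValueError("topology summary of an empty node set")
    for v in nodes:
        _require_node(network, v)
    btw = betweenness_all(network)
    eig = eigenvector_centrality(network)
    clust = nx.clustering(network, nodes)
    return TopologySummary(
        mean_degree=float(np.mean([network.degree(v) for v in nodes])),
        mean_clustering=float(np.mean([clust[v] for v in nodes])),
        mean_betweenness=float(np.mean([btw[v] for v in nodes])),
        mean_eigenvector=float(np.mean([eig[v] for v in nodes])),
        mean_shortest_path=mean_within_set_distance(network, nodes),
    )


def random_matched_baseline(
    network: nx.Graph, size: int, n_sets: int, seed: int
) -> RandomSetBaseline:
    """Descriptor means/stds over ``n_sets`` uniform node samples of ``size``."""
    if size > network.number_of_nodes():
        raise ValueError(
            f"sample size {size} exceeds network size {network.number_of_nodes()}"
        )
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    all_nodes = sorted(network.nodes)
    # node-level descriptors are sample-independent: compute once
    btw = betweenness_all(network)
    eig = eigenvector_centrality(network)
    clust = nx.clustering(network)
    values: dict[str, list[float]] = {d: [] for d in _DESCRIPTORS}
    for _ in range(n_sets):
        sample = sorted(rng.choice(all_nodes, size=size, replace=False))
        values["mean_degree"].append(float(np.mean([network.degree(v) for v in sample])))
        values["mean_clustering"].append(float(np.mean([clust[v] for v in sample])))
        values["mean_betweenness"].append(float(np.mean([btw[v] for v in sample])))
        values["mean_eigenvector"].append(float(np.mean([eig[v] for v in sample])))
        values["mean_shortest_path"].append(mean_within_set_distance(network, sample))
    means = {d: float(np.nanmean(values[d])) for d in _DESCRIPTORS}
    stds = {d: float(np.nanstd(values[d])) for d in _DESCRIPTORS}
    return RandomSetBaseline(n_sets=n_sets, size=size, seed=seed, means=means, stds=stds)
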