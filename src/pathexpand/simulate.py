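"""Synthetic benchmark generation with known ground truth.

The generator plants communities in a stochastic block model: within each
community, node pairs are joined with probability ``p_in``; every other pair
(across communities and involving background nodes) with ``p_out``.  With
``p_in >> p_out`` each community is exactly the kind of densely
interconnected protein set the extension procedure is designed to recover,
so hiding a fraction of each community's members yields a benchmark where
the correct extension is known.

A toy ontology (rooted tree) assigns each community its own subtree of
terms, so that genuinely related proteins carry semantically similar
annotations; background nodes are annotated uniformly across the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .netio import GeneSet, write_gmt
from .semsim import Ontology

__all__ = [
    "PlantedNetworkSpec",
    "GroundTruth",
    "DEFAULT_SPEC",
    "generate_planted_network",
    "emit_incomplete_gmt",
    "generate_toy_ontology",
    "write_obo",
    "write_benchmark",
]


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the planted-community (stochastic block model) network."""

    n_communities: int = 5
    community_size: int = 20
    p_in: float = 0.3
    p_out: float = 0.01
    background_nodes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_communities < 1 or self.community_size < 2:
            raise ValueError("need >= 1 community of >= 2 nodes")


DEFAULT_SPEC = PlantedNetworkSpec()


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the method is asked to recover."""

    true_communities: tuple[frozenset[str], ...]
    hidden_members: Mapping[str, frozenset[str]]  # set_id -> withheld members
    term_assignment: Mapping[str, frozenset[str]]  # set_id -> subtree terms

    def community_id(self, index: int) -> str:
        return f"community_{index + 1:02d}"


def _node_names(spec: PlantedNetworkSpec) -> tuple[list[list[str]], list[str]]:
    communities = [
        [f"C{i + 1:02d}_{j:03d}" for j in range(spec.community_size)]
        for i in range(spec.n_communities)
    ]
    background = [f"B{j:03d}" for j in range(spec.background_nodes)]
    return communities, background


def generate_planted_network(
    spec: PlantedNetworkSpec = DEFAULT_SPEC,
) -> tuple[nx.Graph, GroundTruth]:
    """Draw a stochastic-block-model network with planted communities.

    Background nodes form one extra block whose internal and external edge
    probability is ``p_out``.  Reproducible given ``spec.seed``.
    """
    sizes = [spec.community_size] * spec.n_communities
    probs = [
        [spec.p_in if i == j else spec.p_out for j in range(spec.n_communities)]
        for i in range(spec.n_communities)
    ]
    if spec.background_nodes:
        sizes.append(spec.background_nodes)
        for row in probs:
            row.append(spec.p_out)
        probs.append([spec.p_out] * (spec.n_communities + 1))
    block_graph = nx.stochastic_block_model(
        sizes, probs, seed=int(spec.seed), selfloops=False
    )
    communities, background = _node_names(spec)
    flat = [name for block in communities for name in block] + background
    graph = nx.relabel_nodes(block_graph, dict(enumerate(flat)), copy=True)
    # drop SBM block bookkeeping so the graph is a plain network
    graph.graph.clear()
    truth = GroundTruth(
        true_communities=tuple(frozenset(block) for block in communities),
        hidden_members={},
        term_assignment={},
    )
    return graph, truth


def emit_incomplete_gmt(
    ground_truth: GroundTruth,
    hide_fraction: float,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GeneSet], GroundTruth]:
    """Withhold ``ceil(hide_fraction * size)`` members per community.

    Returns the incomplete gene sets and a new GroundTruth whose
    ``hidden_members`` manifest records the withheld proteins; emitted and
    hidden members partition each true community.
    """
    if not 0 <= hide_fraction < 1:
        raise ValueError("hide_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    hidden: dict[str, frozenset[str]] = {}
    for i, community in enumerate(ground_truth.true_communities):
        set_id = ground_truth.community_id(i)
        members = sorted(community)
        n_hide = math.ceil(hide_fraction * len(members))
        idx = rng.choice(len(members), size=n_hide, replace=False) if n_hide else []
        withheld = frozenset(members[k] for k in idx)
        hidden[set_id] = withheld
        sets.append(
            GeneSet(
                set_id=set_id,
                name=f"planted community {i + 1}",
                members=frozenset(members) - withheld,
            )
        )
    truth = GroundTruth(
        true_communities=ground_truth.true_communities,
        hidden_members=hidden,
        term_assignment=dict(ground_truth.term_assignment),
    )
    return sets, truth


def generate_toy_ontology(
    depth: int,
    branching: int,
    seed: int | np.random.Generator = 0,
    communities: Sequence[frozenset[str]] = (),
    background: Sequence[str] = (),
    namespace: str = "biological_process",
) -> tuple[Ontology, dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Build a rooted tree ontology and community-coherent annotations.

    Each community is assigned one depth-1 subtree (cycling when there are
    more communities than branches); its members are annotated to 1-2 random
    terms of that subtree.  Background proteins are annotated to random terms
    anywhere in the tree.  Returns (ontology, protein->terms annotations,
    community-index-keyed term assignment).
    """
    if depth < 1 or branching < 2:
        raise ValueError("need depth >= 1 and branching >= 2")
    rng = np.random.default_rng(seed)
    root = "T:0000000"
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    level = [root]
    counter = 1
    subtree_terms: list[set[str]] = []
    for d in range(depth):
        next_level = []
        for parent in level:
            for _ in range(branching):
                term = f"T:{counter:07d}"
                counter += 1
                parents[term] = frozenset({parent})
                next_level.append(term)
                if d == 0:
                    subtree_terms.append({term})
                else:
                    for st in subtree_terms:
                        if parent in st:
                            st.add(term)
                            break
        level = next_level
    ontology = Ontology(
        parents=parents, namespace={t: namespace for t in parents}
    )
    annotations: dict[str, frozenset[str]] = {}
    assignment: dict[str, frozenset[str]] = {}
    for i, community in enumerate(communities):
        subtree = sorted(subtree_terms[i % len(subtree_terms)])
        assignment[f"community_{i + 1:02d}"] = frozenset(subtree)
        for protein in sorted(community):
            k = int(rng.integers(1, min(2, len(subtree)) + 1))
            idx = rng.choice(len(subtree), size=k, replace=False)
            annotations[protein] = frozenset(subtree[j] for j in idx)
    all_terms = sorted(set(parents) - {root})
    for protein in background:
        idx = rng.choice(len(all_terms), size=1)
        annotations[protein] = frozenset(all_terms[j] for j in idx)
    return ontology, annotations, assignment


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write a minimal OBO 1.2 flat file (id / name / namespace / is_a)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        handle.write("ontology: synthetic\n")
        for term in sorted(ontology.terms):
            handle.write("\n[Term]\n")
            handle.write(f"id: {term}\n")
            handle.write(f"name: synthetic term {term}\n")
            handle.write(f"namespace: {ontology.namespace[term]}\n")
            for parent in sorted(ontology.parents[term]):
                handle.write(f"is_a: {parent} ! synthetic term {parent}\n")


def write_benchmark(
    outdir: str | Path,
    spec: PlantedNetworkSpec = DEFAULT_SPEC,
    hide_fraction: float = 0.1,
    n_mutated_background: int = 10,
) -> dict[str, Path]:
    """Generate and write the complete synthetic benchmark to ``outdir``.

    Writes ``edges.tsv`` (network), ``sets.gmt`` (incomplete communities),
    ``hidden.tsv`` (withheld-member manifest), ``ontology.obo`` and
    ``annotations.tsv`` (toy GO-style annotation), and ``mutated.txt`` (a
    gene list combining the hidden members with random background genes, for
    enrichment runs).  All randomness derives from ``spec.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    network, truth = generate_planted_network(spec)
    sets, truth = emit_incomplete_gmt(truth, hide_fraction, rng)
    communities, background = _node_names(spec)
    ontology, annotations, assignment = generate_toy_ontology(
        depth=2,
        branching=max(2, spec.n_communities),
        seed=rng,
        communities=truth.true_communities,
        background=background,
    )

    paths = {name: outdir / fname for name, fname in [
        ("edges", "edges.tsv"),
        ("sets", "sets.gmt"),
        ("hidden", "hidden.tsv"),
        ("ontology", "ontology.obo"),
        ("annotations", "annotations.tsv"),
        ("mutated", "mutated.txt"),
    ]}

    with open(paths["edges"], "w", encoding="utf-8") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            handle.write(f"{a}\t{b}\n")
    write_gmt(sets, paths["sets"])
    with open(paths["hidden"], "w", encoding="utf-8") as handle:
        for set_id in sorted(truth.hidden_members):
            for member in sorted(truth.hidden_members[set_id]):
                handle.write(f"{set_id}\t{member}\n")
    write_obo(ontology, paths["ontology"])
    with open(paths["annotations"], "w", encoding="utf-8") as handle:
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                handle.write(f"{protein}\t{term}\n")
    mutated = sorted(m for hs in truth.hidden_members.values() for m in hs)
    if background and n_mutated_background:
        idx = rng.choice(
            len(background), size=min(n_mutated_background, len(background)),
            replace=False,
        )
        mutated += sorted(background[i] for i in idx)
    with open(paths["mutated"], "w", encoding="utf-8") as handle:
        handle.write("\n".join(mutated) + "\n")
    return paths
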