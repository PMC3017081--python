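"""The pathway extension algorithm.

A mapped gene set is extended with network neighbours in two stages:

1. **Candidate filter.**  Every direct neighbour of a set member is a
   candidate.  A candidate ``v`` is admitted when it has degree > 1
   (condition 1) and satisfies at least one of three association criteria
   against the mapped set ``p`` and thresholds ``T1, T2, T3``:

   * condition 2 (strong-community): ``process_links(v,p) / outside_links(v,p) > T1``
     -- for ``T1 = 1`` this is the classical "strong community" requirement
     that a node has more links into the community than out of it;
   * condition 3 (triangle ratio): the fraction of realised triangles
     (v, set member, other candidate) among the potential ones exceeds ``T2``;
   * condition 4 (node coverage): ``v`` is adjacent to more than a fraction
     ``T3`` of the mapped members.

2. **Greedy compactness growth.**  Among admitted candidates, the one whose
   addition most reduces the compactness score -- the mean shortest-path
   length over all unordered pairs of the set, measured in the full network --
   is added first; the loop stops when no remaining candidate strictly reduces
   the score.  Unreachable pairs contribute a penalty distance so that
   candidates bridging disconnected parts of a pathway always reduce the score.

The filter is evaluated once against the original mapped set; the candidate
pool is not re-grown as members are added.  The algorithm is deterministic:
ties in the greedy step are broken by lexicographic node id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .netio import GeneSet, MappedGeneSet, map_gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "ExtensionConfig",
    "CandidateStats",
    "ExtensionResult",
    "CollectionSummary",
    "candidate_set",
    "evaluate_candidate",
    "first_filter",
    "compact_score",
    "extend_set",
    "extend_collection",
]

DEFAULT_T1 = 1.0
DEFAULT_T2 = 0.1
DEFAULT_T3 = 0.3
DEFAULT_MIN_SET_SIZE = 10


@dataclass(frozen=True)
class ExtensionConfig:
    """Thresholds and options of the extension procedure.

    ``t1`` bounds the in/out link ratio (condition 2), ``t2`` the realised
    triangle fraction (condition 3) and ``t3`` the member coverage
    (condition 4); the defaults 1.0 / 0.1 / 0.3 trade extension count against
    extension size.  ``min_set_size`` is the minimum *original* membership for
    a set to be examined.  ``unreachable_penalty_mode`` selects the distance
    charged to unreachable pairs inside the compactness score: the network
    node count (``node_count``) or a fixed constant (``fixed`` +
    ``fixed_penalty``).
    """

    t1: float = DEFAULT_T1
    t2: float = DEFAULT_T2
    t3: float = DEFAULT_T3
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    unreachable_penalty_mode: str = "node_count"
    fixed_penalty: float = 1000.0

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError("t1 must be positive")
        if not 0 < self.t2 < 1:
            raise ValueError("t2 must lie in (0, 1)")
        if not 0 < self.t3 < 1:
            raise ValueError("t3 must lie in (0, 1): full coverage is 1")
        if self.min_set_size < 2:
            raise ValueError("min_set_size must be >= 2")
        if self.unreachable_penalty_mode not in ("node_count", "fixed"):
            raise ValueError("unreachable_penalty_mode must be 'node_count' or 'fixed'")

    def penalty(self, network: nx.Graph) -> float:
        if self.unreachable_penalty_mode == "node_count":
            return float(network.number_of_nodes())
        return self.fixed_penalty


@dataclass(frozen=True)
class CandidateStats:
    """Per-candidate counts and the filter conditions they satisfy."""

    candidate: str
    degree: int
    process_links: int
    outside_links: int
    triangle_links: int
    possible_triangles: int
    process_node_count: int
    passed_conditions: frozenset[int]

    @property
    def admitted(self) -> bool:
        return 1 in self.passed_conditions and bool(
            self.passed_conditions & {2, 3, 4}
        )


@dataclass(frozen=True)
class ExtensionResult:
    """Outcome of extending one mapped gene set."""

    set_id: str
    original_mapped: frozenset[str]
    added: tuple[str, ...]
    compactness_trajectory: tuple[float, ...]
    candidate_diagnostics: tuple[CandidateStats, ...]
    config_used: ExtensionConfig

    @property
    def extended_members(self) -> frozenset[str]:
        return self.original_mapped | frozenset(self.added)


def candidate_set(network: nx.Graph, mapped_set: Iterable[str]) -> set[str]:
    """All non-member nodes adjacent to at least one mapped member."""
    members = set(mapped_set)
    out: set[str] = set()
    for m in members:
        out.update(network.neighbors(m))
    return out - members


def evaluate_candidate(
    network: nx.Graph,
    mapped_set: Iterable[str],
    candidate_pool: Iterable[str],
    v: str,
    config: ExtensionConfig | None = None,
) -> CandidateStats:
    """Compute the filter counts and condition outcomes for one candidate.

    ``triangle_links`` counts pairs (u, w) with u an in-set neighbour of v, w
    another candidate adjacent to v, and the u-w edge present;
    ``possible_triangles`` counts all such pairs regardless of the u-w edge,
    i.e. triangles that would close if the u-w edge existed.
    """
    config = config or ExtensionConfig()
    members = set(mapped_set)
    pool = set(candidate_pool)
    if v not in pool:
        raise ValueError(f"{v!r} is not in the candidate pool")

    neighbours = set(network.neighbors(v))
    in_set = neighbours & members
    co_candidates = (neighbours & pool) - {v}
    degree = len(neighbours)
    process_links = len(in_set)
    outside_links = degree - process_links
    triangle_links = sum(
        1 for u in in_set for w in co_candidates if network.has_edge(u, w)
    )
    possible_triangles = len(in_set) * len(co_candidates)

    passed: set[int] = set()
    if degree > 1:
        passed.add(1)
    # ratio with zero denominator counts as +inf, i.e. a pass when links exist
    if (outside_links == 0 and process_links > 0) or (
        outside_links > 0 and process_links > config.t1 * outside_links
    ):
        passed.add(2)
    if possible_triangles > 0 and triangle_links / possible_triangles > config.t2:
        passed.add(3)
    if members and process_links / len(members) > config.t3:
        passed.add(4)

    return CandidateStats(
        candidate=v,
        degree=degree,
        process_links=process_links,
        outside_links=outside_links,
        triangle_links=triangle_links,
        possible_triangles=possible_triangles,
        process_node_count=len(members),
        passed_conditions=frozenset(passed),
    )


def first_filter(
    network: nx.Graph,
    mapped_set: Iterable[str],
    config: ExtensionConfig | None = None,
) -> tuple[list[CandidateStats], list[CandidateStats]]:
    """Evaluate every candidate; return (admitted, all diagnostics).

    A candidate is admitted when it passes condition 1 and at least one of
    conditions 2-4.
    """
    config = config or ExtensionConfig()
    members = set(mapped_set)
    pool = candidate_set(network, members)
    diagnostics = [
        evaluate_candidate(network, members, pool, v, config) for v in sorted(pool)
    ]
    admitted = [stats for stats in diagnostics if stats.admitted]
    return admitted, diagnostics


def compact_score(
    network: nx.Graph,
    node_set: Iterable[str],
    config: ExtensionConfig | None = None,
) -> float:
    """Mean shortest-path length over all unordered pairs of the set.

    Distances are measured in the full network, not the induced subgraph; an
    unreachable pair contributes the configured penalty distance.
    """
    config = config or ExtensionConfig()
    nodes = sorted(set(node_set))
    if len(nodes) < 2:
        raise ValueError("compact_score needs at least 2 nodes")
    penalty = config.penalty(network)
    total = 0.0
    for i, s in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(network, s)
        for t in nodes[i + 1 :]:
            total += dist.get(t, penalty)
    n = len(nodes)
    return total / (n * (n - 1) / 2)


def _pair_distances(
    network: nx.Graph, sources: Sequence[str], targets: set[str], penalty: float
) -> dict[str, dict[str, float]]:
    """Distance (with penalty fill-in) from each source to each target."""
    out: dict[str, dict[str, float]] = {}
    for s in sources:
        dist = nx.single_source_shortest_path_length(network, s)
        out[s] = {t: float(dist.get(t, penalty)) for t in targets}
    return out


def extend_set(
    network: nx.Graph,
    mapped_set: Iterable[str] | MappedGeneSet,
    config: ExtensionConfig | None = None,
    set_id: str = "",
) -> ExtensionResult:
    """Run the full extension procedure on one mapped set.

    The compactness trajectory starts with the score of the original mapped
    set and appends the score after each accepted addition; it is strictly
    decreasing after position 0 by construction.
    """
    config = config or ExtensionConfig()
    if isinstance(mapped_set, MappedGeneSet):
        set_id = set_id or mapped_set.set_id
        members = set(mapped_set.mapped_members)
    else:
        members = set(mapped_set)
    if len(members) < 2:
        raise ValueError("extension needs >= 2 mapped members")

    admitted, diagnostics = first_filter(network, members, config)
    penalty = config.penalty(network)

    # distances are static, so one BFS per involved node suffices for the
    # whole greedy loop
    involved = sorted(members | {s.candidate for s in admitted})
    dmat = _pair_distances(network, involved, set(involved), penalty)

    current = sorted(members)
    pair_sum = sum(
        dmat[s][t] for i, s in enumerate(current) for t in current[i + 1 :]
    )
    n = len(current)
    score = pair_sum / (n * (n - 1) / 2)
    trajectory = [score]
    remaining = {s.candidate for s in admitted}
    added: list[str] = []
    current_set = set(current)

    while remaining:
        best_node = None
        best_score = score
        for v in sorted(remaining):
            cand_sum = pair_sum + sum(dmat[v][u] for u in current_set)
            k = n + 1
            cand_score = cand_sum / (k * (k - 1) / 2)
            if cand_score < best_score:  # strict improvement; ties keep earlier id
                best_score = cand_score
                best_node = v
        if best_node is None:
            break
        pair_sum += sum(dmat[best_node][u] for u in current_set)
        current_set.add(best_node)
        n += 1
        score = best_score
        trajectory.append(score)
        added.append(best_node)
        remaining.remove(best_node)

    return ExtensionResult(
        set_id=set_id,
        original_mapped=frozenset(members),
        added=tuple(added),
        compactness_trajectory=tuple(trajectory),
        candidate_diagnostics=tuple(diagnostics),
        config_used=config,
    )


@dataclass(frozen=True)
class CollectionSummary:
    """Aggregate statistics over a collection extension run."""

    n_sets: int
    n_examined: int
    n_extended: int
    avg_size_before: float
    avg_size_after: float
    total_added: int
    unique_added: int


def extend_collection(
    network: nx.Graph,
    sets: Sequence[GeneSet],
    config: ExtensionConfig | None = None,
) -> tuple[list[ExtensionResult], CollectionSummary]:
    """Extend every eligible set of a collection.

    Sets with fewer than ``config.min_set_size`` original members, or with
    fewer than 2 members mapped onto the network, are skipped.  Average sizes
    refer to mapped membership before and after extension, over examined sets.
    """
    config = config or ExtensionConfig()
    results: list[ExtensionResult] = []
    sizes_before: list[int] = []
    sizes_after: list[int] = []
    all_added: list[str] = []
    n_extended = 0
    for gs in sets:
        if len(gs.members) < config.min_set_size:
            continue
        mapped = map_gene_set(network, gs)
        if len(mapped.mapped_members) < 2:
            logger.info("skipping %s: fewer than 2 mapped members", gs.set_id)
            continue
        result = extend_set(network, mapped, config)
        results.append(result)
        sizes_before.append(len(result.original_mapped))
        sizes_after.append(len(result.extended_members))
        all_added.extend(result.added)
        if result.added:
            n_extended += 1
    n_examined = len(results)
    summary = CollectionSummary(
        n_sets=len(sets),
        n_examined=n_examined,
        n_extended=n_extended,
        avg_size_before=sum(sizes_before) / n_examined if n_examined else float("nan"),
        avg_size_after=sum(sizes_after) / n_examined if n_examined else float("nan"),
        total_added=len(all_added),
        unique_added=len(set(all_added)),
    )
    return results, summary


def diagnostics_table(results: Sequence[ExtensionResult]) -> pd.DataFrame:
    """One row per (set, candidate) with all filter counts."""
    rows = []
    for res in results:
        for s in res.candidate_diagnostics:
            rows.append(
                {
                    "set_id": res.set_id,
                    "candidate": s.candidate,
                    "degree": s.degree,
                    "process_links": s.process_links,
                    "outside_links": s.outside_links,
                    "triangle_links": s.triangle_links,
                    "possible_triangles": s.possible_triangles,
                    "process_node_count": s.process_node_count,
                    "passed_conditions": ",".join(map(str, sorted(s.passed_conditions))),
                    "admitted": s.admitted,
                    "added": s.candidate in res.added,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "candidate",
            "degree",
            "process_links",
            "outside_links",
            "triangle_links",
            "possible_triangles",
            "process_node_count",
            "passed_conditions",
            "admitted",
            "added",
        ],
    )
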