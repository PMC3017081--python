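"""Jiang-Conrath semantic similarity between original and added proteins.

Annotation-based information content: ``IC(t) = -ln p(t)`` where ``p(t)`` is
the fraction of annotated proteins in the term's namespace annotated to ``t``
or any of its descendants (annotations propagate to all ancestors).  The
Jiang-Conrath distance between two terms is

    d(t1, t2) = IC(t1) + IC(t2) - 2 * IC(MICA)

with MICA the common ancestor of maximal IC.  Distances are mapped to
similarities via ``sim = 1 / (1 + d)``, which is bounded in (0, 1] and equals
1 exactly for identical terms.  Set-level similarity averages ``sim`` over all
pairs of distinct terms annotated to the two protein sets.

The validation compares, per extended set, the similarity between original
and added proteins against size-matched random draws from the set's candidate
pool (excluding the extended membership); the empirical p-value is the
fraction of draws at least as similar as the real extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .expander import ExtensionResult, candidate_set

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "SetSemSim",
    "SemSimReport",
    "read_obo",
    "read_annotations",
    "read_gaf",
    "information_content",
    "jc_distance",
    "set_similarity",
    "semsim_validation",
]

AnnotationMap = Mapping[str, frozenset[str]]


@dataclass(frozen=True)
class Ontology:
    """A DAG of terms connected by is_a edges, one namespace per term."""

    parents: Mapping[str, frozenset[str]]  # term -> direct is_a parents
    namespace: Mapping[str, str]

    def __post_init__(self) -> None:
        graph = nx.DiGraph(
            (child, parent)
            for child, ps in self.parents.items()
            for parent in ps
        )
        graph.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("is_a relation contains a cycle")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents[t])
        return frozenset(out)

    def descendants(self, term: str) -> frozenset[str]:
        """All descendants of ``term`` including itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        children: dict[str, set[str]] = {t: set() for t in self.parents}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].add(child)
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(children[t])
        return frozenset(out)


def read_obo(path: str | Path) -> Ontology:
    """Read an OBO 1.2 flat file (id / is_a / namespace tags)."""
    graph = obonet.read_obo(path)
    parents = {
        term: frozenset(
            parent
            for _, parent, key in graph.out_edges(term, keys=True)
            if key == "is_a"
        )
        for term in graph.nodes
    }
    namespace = {
        term: data.get("namespace", "default")
        for term, data in graph.nodes(data=True)
    }
    return Ontology(parents=parents, namespace=namespace)


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a 2-column protein TAB term annotation file."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: annotation lines need 2 fields")
            out.setdefault(fields[0], set()).add(fields[1])
    return {p: frozenset(ts) for p, ts in out.items()}


def read_gaf(path: str | Path, aspect: str | None = None) -> dict[str, frozenset[str]]:
    """Read a GAF 2.x file (column 2 = protein, 5 = term, 9 = aspect)."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: GAF lines need >= 9 columns")
            if aspect is not None and fields[8] != aspect:
                continue
            out.setdefault(fields[1], set()).add(fields[4])
    return {p: frozenset(ts) for p, ts in out.items()}


class _ICIndex:
    """Cached IC values for one (ontology, annotations) corpus."""

    def __init__(self, ontology: Ontology, annotations: AnnotationMap) -> None:
        self.ontology = ontology
        # usage[t] = number of proteins annotated to t or any descendant
        usage: dict[str, set[str]] = {t: set() for t in ontology.terms}
        ns_proteins: dict[str, set[str]] = {}
        for protein, terms in annotations.items():
            for term in terms:
                if term not in ontology.terms:
                    raise KeyError(f"annotation to unknown term {term!r}")
                for anc in ontology.ancestors(term):
                    usage[anc].add(protein)
                ns_proteins.setdefault(ontology.namespace[term], set()).add(protein)
        self.usage = {t: len(ps) for t, ps in usage.items()}
        self.ns_total = {ns: len(ps) for ns, ps in ns_proteins.items()}

    def ic(self, term: str) -> float:
        count = self.usage.get(term)
        if count is None:
            raise KeyError(f"unknown term {term!r}")
        if count == 0:
            raise ValueError(f"term {term!r} annotates no protein; IC undefined")
        total = self.ns_total[self.ontology.namespace[term]]
        return -log(count / total)


def information_content(
    ontology: Ontology, annotations: AnnotationMap, term: str
) -> float:
    """-ln of the term's annotation frequency (descendants included)."""
    return _ICIndex(ontology, annotations).ic(term)


def _jc_distance_indexed(index: _ICIndex, t1: str, t2: str) -> float:
    ontology = index.ontology
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    common = {t for t in common if index.usage.get(t, 0) > 0}
    if not common:
        raise ValueError(f"terms {t1!r} and {t2!r} share no common ancestor")
    mica_ic = max(index.ic(t) for t in common)
    return index.ic(t1) + index.ic(t2) - 2 * mica_ic


def jc_distance(
    ontology: Ontology, annotations: AnnotationMap, t1: str, t2: str
) -> float:
    """Jiang-Conrath distance IC(t1)+IC(t2)-2*IC(MICA); 0 for identical terms."""
    return _jc_distance_indexed(_ICIndex(ontology, annotations), t1, t2)


def _set_similarity_indexed(
    index: _ICIndex,
    annotations: AnnotationMap,
    proteins_a: Iterable[str],
    proteins_b: Iterable[str],
    namespace: str | None,
) -> float:
    ontology = index.ontology

    def term_union(proteins: Iterable[str]) -> list[str]:
        terms: set[str] = set()
        dropped = 0
        for p in proteins:
            ts = annotations.get(p)
            if not ts:
                dropped += 1
                continue
            for t in ts:
                if namespace is None or ontology.namespace[t] == namespace:
                    terms.add(t)
        if dropped:
            logger.debug("dropped %d unannotated proteins", dropped)
        return sorted(terms)

    terms_a = term_union(proteins_a)
    terms_b = term_union(proteins_b)
    if not terms_a or not terms_b:
        raise ValueError("no annotated protein on one side of the comparison")
    sims = [
        1.0 / (1.0 + _jc_distance_indexed(index, ta, tb))
        for ta in terms_a
        for tb in terms_b
    ]
    return float(np.mean(sims))


def set_similarity(
    ontology: Ontology,
    annotations: AnnotationMap,
    proteins_a: Iterable[str],
    proteins_b: Iterable[str],
    namespace: str | None = None,
) -> float:
    """Mean pairwise term similarity between two protein sets.

    Each distinct (term of a, term of b) pair in the namespace is counted
    once; unannotated proteins are dropped.
    """
    index = _ICIndex(ontology, annotations)
    return _set_similarity_indexed(index, annotations, proteins_a, proteins_b, namespace)


@dataclass(frozen=True)
class SetSemSim:
    set_id: str
    real_similarity: float
    random_similarities: tuple[float, ...]
    empirical_p: float


@dataclass(frozen=True)
class SemSimReport:
    per_set: tuple[SetSemSim, ...]
    n_random: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "set_id": s.set_id,
                "real_similarity": s.real_similarity,
                "mean_random_similarity": (
                    float(np.mean(s.random_similarities))
                    if s.random_similarities
                    else float("nan")
                ),
                "empirical_p": s.empirical_p,
            }
            for s in self.per_set
        ]
        return pd.DataFrame(
            rows,
            columns=["set_id", "real_similarity", "mean_random_similarity", "empirical_p"],
        )


def semsim_validation(
    network: nx.Graph,
    extension_results: Sequence[ExtensionResult],
    ontology: Ontology,
    annotations: AnnotationMap,
    n_random: int = 100,
    seed: int = 0,
    namespace: str | None = None,
) -> SemSimReport:
    """Compare original-vs-added similarity against a random-candidate null.

    Null draws sample ``|added|`` proteins from the candidate pool of the
    original set, excluding the extended membership.  Sets with no additions
    (or with no usable null draw) are skipped with a log notice.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    index = _ICIndex(ontology, annotations)
    per_set: list[SetSemSim] = []
    for result in extension_results:
        if not result.added:
            logger.info("skipping %s: empty extension", result.set_id)
            continue
        try:
            real = _set_similarity_indexed(
                index, annotations, result.original_mapped, result.added, namespace
            )
        except ValueError:
            logger.info("skipping %s: no annotated protein", result.set_id)
            continue
        pool = sorted(
            candidate_set(network, result.original_mapped) - result.extended_members
        )
        k = min(len(result.added), len(pool))
        randoms: list[float] = []
        for _ in range(n_random):
            if k == 0:
                break
            idx = rng.choice(len(pool), size=k, replace=False)
            sample = [pool[i] for i in idx]
            try:
                randoms.append(
                    _set_similarity_indexed(
                        index, annotations, result.original_mapped, sample, namespace
                    )
                )
            except ValueError:
                # draw without annotated proteins: no similarity defined
                continue
        if not randoms:
            logger.info("skipping %s: no usable null draw", result.set_id)
            continue
        empirical_p = float(np.mean([r >= real for r in randoms]))
        per_set.append(
            SetSemSim(
                set_id=result.set_id,
                real_similarity=real,
                random_similarities=tuple(randoms),
                empirical_p=empirical_p,
            )
        )
    return SemSimReport(per_set=tuple(per_set), n_random=n_random, seed=seed)
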