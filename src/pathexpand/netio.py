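"""Readers and writers for interaction networks, gene sets and the mapping step.

Networks are plain :class:`networkx.Graph` objects over opaque string
identifiers.  All readers enforce graph simplicity: self-loops and duplicate
edges are dropped silently (with counts logged at INFO level), and adjacency is
symmetric by construction.  No identifier translation is performed anywhere --
the edge list and the gene sets must share one pre-harmonised namespace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "MappedGeneSet",
    "ParseError",
    "read_edge_list",
    "read_psimitab",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "map_gene_set",
    "mapping_report",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named pathway/process: an identifier, a description and its members."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class MappedGeneSet:
    """A gene set restricted to the nodes present in a given network."""

    origin: GeneSet
    mapped_members: frozenset[str]
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.mapped_members <= self.origin.members:
            raise ValueError("mapped members must be a subset of the original members")
        object.__setattr__(
            self, "coverage", len(self.mapped_members) / len(self.origin.members)
        )

    @property
    def set_id(self) -> str:
        return self.origin.set_id


def _build_graph(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    graph = nx.Graph()
    n_loops = 0
    n_dupes = 0
    for a, b in pairs:
        if a == b:
            n_loops += 1
            continue
        if graph.has_edge(a, b):
            n_dupes += 1
            continue
        graph.add_edge(a, b)
    if n_loops or n_dupes:
        logger.info("dropped %d self-loops and %d duplicate edges", n_loops, n_dupes)
    return graph


def read_edge_list(path: str | Path, delimiter: str = "\t") -> nx.Graph:
    """Read a 2+-column edge list into a simple undirected graph.

    Lines starting with ``#`` and blank lines are ignored.  Columns beyond the
    first two are allowed and ignored.  Self-loops and duplicate pairs
    (regardless of orientation) are dropped.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter != " " else line.split()
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 fields, got {len(fields)}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return _build_graph(pairs)


def read_psimitab(path: str | Path, strip_prefix: bool = True) -> nx.Graph:
    """Read a minimal PSI-MI TAB 2.5 file (interactors in columns 1-2).

    Identifier namespace prefixes such as ``uniprotkb:`` are stripped when
    ``strip_prefix`` is true.  Only the first two columns are interpreted; the
    remaining MITAB columns are ignored.
    """

    def clean(raw: str) -> str:
        raw = raw.strip()
        if strip_prefix and ":" in raw:
            raw = raw.split(":", 1)[1]
        return raw

    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}: line {lineno}: missing interactor column"
                )
            pairs.append((clean(fields[0]), clean(fields[1])))
    return _build_graph(pairs)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (``set_id TAB description TAB member...``)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT lines need >=3 fields, got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            if set_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(set_id=set_id, name=name, members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format (members sorted for reproducibility)."""
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            handle.write(
                "\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n"
            )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a flat gene list, one identifier per line; '#' comments skipped."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            gene = line.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    return genes


def map_gene_set(network: nx.Graph, gene_set: GeneSet) -> MappedGeneSet:
    """Restrict a gene set to the nodes present in the network."""
    mapped = frozenset(m for m in gene_set.members if network.has_node(m))
    return MappedGeneSet(origin=gene_set, mapped_members=mapped)


def mapping_report(network: nx.Graph, sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Per-set mapping coverage table with the collection mean.

    Returns one row per set (``set_id, size, mapped_size, coverage``).  The
    mean coverage across sets is stored in ``df.attrs["mean_coverage"]``
    (NaN for an empty collection).
    """
    rows = []
    for gs in sets:
        mapped = map_gene_set(network, gs)
        rows.append(
            {
                "set_id": gs.set_id,
                "size": len(gs.members),
                "mapped_size": len(mapped.mapped_members),
                "coverage": mapped.coverage,
            }
        )
    df = pd.DataFrame(rows, columns=["set_id", "size", "mapped_size", "coverage"])
    df.attrs["mean_coverage"] = float(df["coverage"].mean()) if rows else math.nan
    return df
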