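"""Over-representation analysis of a gene list against gene-set collections.

One-tailed Fisher exact test (upper-tail hypergeometric) per set, with
Benjamini-Hochberg FDR adjustment across each collection, and a before/after
comparison between original and extended sets.  The default universe is the
set of all network proteins.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netio import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["fisher_ora", "benjamini_adjust", "enrich_compare"]


def fisher_ora(
    universe_size: int, set_size: int, list_size: int, overlap: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    Equivalent to the one-tailed Fisher exact test on the 2x2 overlap table.
    """
    if overlap < 0 or overlap > min(set_size, list_size):
        raise ValueError("overlap must lie in [0, min(set_size, list_size)]")
    if set_size > universe_size or list_size > universe_size:
        raise ValueError("set and list sizes cannot exceed the universe size")
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, list_size))


def benjamini_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_compare(
    original_sets: Sequence[GeneSet],
    extended_sets: Sequence[GeneSet],
    gene_list: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Before/after ORA table for an original vs extended collection.

    Both collections must cover the same set ids, with every extended set a
    superset of its original.  The two p-value families (original, extended)
    are BH-adjusted independently.  Genes outside the universe are dropped
    with a logged count.  Rows are sorted by ``q_after``.
    """
    universe = set(universe)
    genes = set(gene_list)
    outside = genes - universe
    if outside:
        logger.info("dropped %d gene-list members outside the universe", len(outside))
        genes &= universe
    orig_by_id = {gs.set_id: gs for gs in original_sets}
    ext_by_id = {gs.set_id: gs for gs in extended_sets}
    if set(orig_by_id) != set(ext_by_id):
        raise ValueError("original and extended collections cover different set ids")
    rows = []
    p_before: list[float] = []
    p_after: list[float] = []
    for set_id in sorted(orig_by_id):
        orig = orig_by_id[set_id].members & universe
        ext = ext_by_id[set_id].members & universe
        if not orig <= ext:
            raise ValueError(f"extended set {set_id!r} is not a superset of the original")
        added = ext - orig
        overlap_before = orig & genes
        overlap_after = ext & genes
        p_b = fisher_ora(len(universe), len(orig), len(genes), len(overlap_before))
        p_a = fisher_ora(len(universe), len(ext), len(genes), len(overlap_after))
        p_before.append(p_b)
        p_after.append(p_a)
        rows.append(
            {
                "set_id": set_id,
                "size_before": len(orig),
                "size_after": len(ext),
                "overlap_before": len(overlap_before),
                "overlap_after": len(overlap_after),
                "p_before": p_b,
                "p_after": p_a,
                "overlap_members": ",".join(sorted(overlap_after)),
                "added_overlap_members": ",".join(sorted(added & genes)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "size_before",
            "size_after",
            "overlap_before",
            "overlap_after",
            "p_before",
            "p_after",
            "overlap_members",
            "added_overlap_members",
        ],
    )
    if not df.empty:
        df["q_before"] = benjamini_adjust(p_before)
        df["q_after"] = benjamini_adjust(p_after)
        df = df.sort_values("q_after", kind="stable").reset_index(drop=True)
    else:
        df["q_before"] = []
        df["q_after"] = []
    return df
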