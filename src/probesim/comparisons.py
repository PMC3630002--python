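"""Comparison designs and per-comparison pair statistics.

A network is built from a fixed series of condition-vs-condition comparisons.
The standard design crosses two disjoint groups of biological conditions
(two groups of 30 give 30x30 = 900 comparisons); the exhaustive design takes
all unordered condition pairs (748 conditions give 748*747/2 = 279378).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import nearest_rank_percentile
from .covariation import VariationCallMatrix

logger = logging.getLogger(__name__)


@dataclass
class ComparisonDesign:
    """Named condition groups plus the ordered comparison list they induce."""

    groups: dict[str, list[str]]
    comparisons: list[tuple[str, str]]
    mode: str  # "cross_group" | "all_pairs"

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def comparison_ids(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.comparisons]


def build_cross_design(
    group_a: Sequence[str], group_b: Sequence[str],
    name_a: str = "A", name_b: str = "B",
) -> ComparisonDesign:
    """Cross two disjoint condition groups: every (a, b) pair, row-major."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("condition groups must be non-empty")
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("duplicate condition identifiers within a group")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"condition groups overlap: {sorted(overlap)}")
    comparisons = [(x, y) for x in a for y in b]
    return ComparisonDesign({name_a: a, name_b: b}, comparisons, "cross_group")


def build_all_pairs_design(conditions: Sequence[str]) -> ComparisonDesign:
    """All unordered condition pairs once, in lexicographic order."""
    conds = list(conditions)
    if len(set(conds)) != len(conds):
        raise ValueError("duplicate condition identifiers")
    if len(conds) < 2:
        raise ValueError("need at least 2 distinct conditions")
    ordered = sorted(conds)
    comparisons = list(itertools.combinations(ordered, 2))
    return ComparisonDesign({"all": ordered}, comparisons, "all_pairs")


def comparison_pair_stats(
    calls: VariationCallMatrix,
    pairs_by_class: Mapping[object, Sequence[tuple[str, str]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of concordant/discordant pairs per comparison and class.

    For each comparison c and similarity class k:
    pcorr = 100 * #{pairs with concordant calls (II/DD) in c} / #pairs in k,
    panti analogous with discordant calls (ID/DI); the denominator is the
    full class membership, including pairs with N calls.  rel is the relative
    share of anti, 100*panti/(pcorr+panti), undefined where both are zero.

    Returns (per_comparison, summary): the long per-comparison table and a
    per-class summary with means and nearest-rank 95th percentiles.
    """
    frames = []
    summaries = []
    for cls, pairs in pairs_by_class.items():
        if len(pairs) == 0:
            logger.warning("similarity class %r has no pairs; omitted", cls)
            continue
        i = np.array([calls.index_of(a) for a, _ in pairs])
        j = np.array([calls.index_of(b) for _, b in pairs])
        prod = calls.codes[i].astype(np.int32) * calls.codes[j]
        npairs = len(pairs)
        pcorr = 100.0 * (prod == 1).sum(axis=0) / npairs
        panti = 100.0 * (prod == -1).sum(axis=0) / npairs
        denom = pcorr + panti
        rel = np.where(denom > 0, 100.0 * panti / np.where(denom > 0, denom, 1.0), np.nan)
        frames.append(pd.DataFrame({
            "comparison_id": calls.comparison_ids,
            "class": cls,
            "pcorr": pcorr,
            "panti": panti,
            "rel": rel,
        }))
        rel_defined = rel[~np.isnan(rel)]
        summaries.append({
            "class": cls,
            "n_pairs": npairs,
            "mean_pcorr": float(pcorr.mean()),
            "p95_pcorr": nearest_rank_percentile(pcorr, 95),
            "mean_panti": float(panti.mean()),
            "p95_panti": nearest_rank_percentile(panti, 95),
            "mean_rel": float(rel_defined.mean()) if rel_defined.size else np.nan,
            "p95_rel": nearest_rank_percentile(rel_defined, 95) if rel_defined.size else np.nan,
        })
    if not frames:
        raise ValueError("no non-empty similarity class supplied")
    per_comparison = pd.concat(frames, ignore_index=True)
    summary = pd.DataFrame(summaries)
    return per_comparison, summary
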