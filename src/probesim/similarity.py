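"""Multi-network similarity test for alternative probe-set pairs.

Bona fide similar alternative probe sets should be positively correlated in
every network.  The pooled per-network values of exactly those pairs supply
the calibration distributions, from which three limits are taken: the 5th
percentile of positive correlations (corr5th), the 95th percentile of
negative correlations (anti95th) and the 95th percentile of the neighbourhood
overlap log10 p-values (overlap95th).  A pair is then similar in network i iff

    corr_i >= corr5th  and  anti_i <= anti95th  and  overlap_i <= overlap95th.

The fraction of networks in which a pair passes maps to a similarity class:
0 (never similar), 1 (at least one network), 25, 50, 75 (at least that
percentage of networks) or 100 (similar in all networks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import nearest_rank_percentile
from .covariation import CovariationNetwork

logger = logging.getLogger(__name__)

SIMILARITY_CLASSES = (0, 1, 25, 50, 75, 100)


@dataclass
class SimilarityLimits:
    """Per-chip similarity test limits calibrated from always-positive pairs."""

    corr_5th: float
    anti_95th: float
    overlap_95th: float
    n_networks: int
    n_calibration_pairs: int

    def rounded(self) -> tuple[int, int, int]:
        """Display form: integer limits."""
        return (round(self.corr_5th), round(self.anti_95th), round(self.overlap_95th))


@dataclass
class PairSimilarity:
    pair: tuple[str, str]
    gene: str
    per_network: list[bool]
    n_similar: int
    similarity_class: int
    mean_corr: float = float("nan")
    mean_anti: float = float("nan")
    mean_overlap: float = float("nan")


def count_positive_networks(
    pair: tuple[str, str], networks: Sequence[CovariationNetwork]
) -> int:
    """Number of networks with a stored significant positive correlation."""
    a, b = pair
    return sum(1 for net in networks if net.has_positive_edge(a, b))


def calibrate_limits(
    corr_values: Sequence[float],
    anti_values: Sequence[float],
    overlap_values: Sequence[float],
    n_networks: int,
    n_calibration_pairs: int,
) -> SimilarityLimits:
    """Nearest-rank percentiles of the pooled calibration distributions.

    The inputs are the per-network corr/anti/log10-overlap values of the
    calibration pairs (pairs positively correlated in all networks), pooled
    over pairs x networks.
    """
    if n_calibration_pairs == 0 or len(corr_values) == 0:
        raise ValueError(
            "empty calibration set: no alternative pair is positively correlated "
            "in all networks; use more networks, more comparisons or more pairs"
        )
    return SimilarityLimits(
        corr_5th=nearest_rank_percentile(corr_values, 5),
        anti_95th=nearest_rank_percentile(anti_values, 95),
        overlap_95th=nearest_rank_percentile(overlap_values, 95),
        n_networks=n_networks,
        n_calibration_pairs=n_calibration_pairs,
    )


def test_pair_in_network(
    corr: float, anti: float, overlap: float, limits: SimilarityLimits
) -> bool:
    """Three-condition similarity test in one network.

    Absent (non-significant) values must be supplied as 0 (corr, anti) and
    0.0 (overlap log10 p, i.e. p = 1).
    """
    return (
        corr >= limits.corr_5th
        and anti <= limits.anti_95th
        and overlap <= limits.overlap_95th
    )


def similarity_class(n_similar: int, n_networks: int) -> int:
    """Map a pass count to the 0/1/25/50/75/100 similarity class.

    0 when never similar, 100 when similar in every network, otherwise the
    largest threshold in {1, 25, 50, 75} met by the percentage of networks
    (1 meaning at least one network).
    """
    if n_networks < 1 or not 0 <= n_similar <= n_networks:
        raise ValueError("need 0 <= n_similar <= n_networks >= 1")
    if n_similar == 0:
        return 0
    if n_similar == n_networks:
        return 100
    pct = 100.0 * n_similar / n_networks
    for t in (75, 50, 25):
        if pct >= t:
            return t
    return 1


def pair_reproducibility(
    classes_a: Mapping[tuple[str, str], int],
    classes_b: Mapping[tuple[str, str], int],
) -> tuple[float | None, float | None]:
    """Reproducibility of the extreme similarity classes between two runs.

    rep0: of the pairs with class 0 in a (and present in b), the percentage
    with class 0 or 1 in b.  rep100: of the pairs with class 100 in a, the
    percentage with class 75 or 100 in b.  A class with no shared pair is
    reported as None.
    """

    def rep(cls: int, equivalent: set[int]) -> float | None:
        tested = [p for p, c in classes_a.items() if c == cls and p in classes_b]
        if not tested:
            return None
        ok = sum(1 for p in tested if classes_b[p] in equivalent)
        return 100.0 * ok / len(tested)

    return rep(0, {0, 1}), rep(100, {75, 100})


def gene_reproducibility(
    classes_a: Mapping[tuple[str, str], int],
    classes_b: Mapping[tuple[str, str], int],
    assignments_a: Mapping[str, str],
    assignments_b: Mapping[str, str],
) -> tuple[float | None, float | None]:
    """Gene-level reproducibility for chips without common probe sets.

    For class c in {0, 100}: candidate genes have all their alternative pairs
    in class c in chip a and at least one alternative pair in chip b; a
    candidate succeeds when all of its chip-b pairs fall in the equivalent
    class set ({0, 1} or {75, 100}).
    """

    def pairs_per_gene(classes, assignments):
        out: dict[str, list[int]] = {}
        for (p1, p2), c in classes.items():
            g1, g2 = assignments.get(p1), assignments.get(p2)
            if g1 is not None and g1 == g2:
                out.setdefault(g1, []).append(c)
        return out

    genes_a = pairs_per_gene(classes_a, assignments_a)
    genes_b = pairs_per_gene(classes_b, assignments_b)

    def rep(cls: int, equivalent: set[int]) -> float | None:
        candidates = [
            g for g, cs in genes_a.items()
            if all(c == cls for c in cs) and g in genes_b
        ]
        if not candidates:
            return None
        ok = sum(
            1 for g in candidates if all(c in equivalent for c in genes_b[g])
        )
        return 100.0 * ok / len(candidates)

    return rep(0, {0, 1}), rep(100, {75, 100})
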