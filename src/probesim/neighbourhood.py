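"""Probe-set neighbourhoods and hypergeometric overlap significance.

The neighbourhood of a probe set in a covariation network is the set of
probe sets it is significantly positively correlated with.  Two probe sets
targeting the same transcripts should recruit overlapping neighbourhoods;
the chance of an overlap of size >= N between neighbourhoods of sizes N1 and
N2 drawn from a universe of M probe sets follows the hypergeometric
distribution, and the evidence is carried as log10 of that tail probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from .covariation import CovariationNetwork

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class OverlapScore:
    n_overlap: int
    n1: int
    n2: int
    population: int
    log10_p: float


def neighbourhood(
    network: CovariationNetwork, ps: str, include_negative: bool = False
) -> set[str]:
    """Probe sets with a stored significant correlation to ``ps``.

    By default only positive (CORR) partners count; ``include_negative``
    additionally admits stored ANTI partners.  The centre itself is excluded.
    """
    i = network.index_of(ps)
    mask = network.stored_corr[i] & (network.corr[i] > 0)
    if include_negative:
        mask = mask | (network.stored_anti[i] & (network.anti[i] > 0))
    out = {network.probe_set_ids[j] for j in mask.nonzero()[0]}
    out.discard(ps)
    return out


def overlap_log_pvalue(n_overlap: int, n1: int, n2: int, population: int) -> float:
    """log10 P(overlap >= n_overlap) under the hypergeometric null.

    p = sum_{k=N..min(N1,N2)} C(N1,k) C(M-N1,N2-k) / C(M,N2), computed in
    log-space so it stays finite for populations up to ~1e5.
    """
    if min(n_overlap, n1, n2, population) < 0:
        raise ValueError("counts must be non-negative")
    if n1 > population or n2 > population:
        raise ValueError("neighbourhood sizes cannot exceed the population")
    if n_overlap > min(n1, n2):
        raise ValueError("overlap cannot exceed the smaller neighbourhood")
    if n_overlap == 0:
        return 0.0
    log_p = hypergeom.logsf(n_overlap - 1, population, n1, n2)
    return float(log_p) / LOG10


def pair_overlap(
    network: CovariationNetwork, ps_a: str, ps_b: str, include_negative: bool = False
) -> OverlapScore:
    """Neighbourhood overlap of two probe sets in one network.

    The population is the number of probe sets in the network; the two
    centres are not members of their own neighbourhoods.
    """
    na = neighbourhood(network, ps_a, include_negative)
    nb = neighbourhood(network, ps_b, include_negative)
    n_overlap = len(na & nb)
    population = network.n_probe_sets
    return OverlapScore(
        n_overlap=n_overlap,
        n1=len(na),
        n2=len(nb),
        population=population,
        log10_p=overlap_log_pvalue(n_overlap, len(na), len(nb), population),
    )
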