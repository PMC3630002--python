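"""Network reduction, Markov clustering and rank-difference analysis.

Similar probe sets can be merged into a single node whose correlations to the
rest of the network are the means of its members' values; the reduced network
is then clustered with Markov clustering (MCL).  MCL alternates expansion
(matrix squaring), inflation (elementwise powering) and pruning (dropping
tiny entries); a pruning score between 0 (much mass discarded) and 100
(none) summarises how lossy the pruning was.  Clustering reproducibility
between two runs is the weighted mean overlap of the largest clusters, with
geometric-mean normalisation.  Rank analysis normalises raw signals to a
0-100 rank scale per biological condition and compares the absolute rank
differences of alternative pairs across similarity classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .covariation import CovariationNetwork
from .grouping import ProbeSetGroup

logger = logging.getLogger(__name__)


@dataclass
class MergedNetwork:
    network: CovariationNetwork
    merge_map: dict[str, str]  # original probe set -> merged node id
    size_reduction: float  # percent


@dataclass
class MclResult:
    clusters: list[set[str]]  # ordered by size descending
    pruning_score: int
    inflation: float
    n_iterations: int


def merge_probe_sets(
    network: CovariationNetwork, groups: Sequence[ProbeSetGroup]
) -> MergedNetwork:
    """Collapse each group to one node; merged correlations are member means.

    Absent (filtered) entries count as 0 in the means; intra-group edges are
    dropped.  Groups must be disjoint (resolve pivots to a single group
    beforehand).  The merged node takes the lexicographically smallest member
    id.
    """
    ids = network.probe_set_ids
    n = len(ids)
    member_of: dict[str, int] = {}
    group_lists: list[list[str]] = []
    for g in groups:
        members = sorted(g.members if isinstance(g, ProbeSetGroup) else g)
        for ps in members:
            if ps in member_of:
                raise ValueError(f"probe set {ps!r} appears in several groups")
            if ps not in network._index:
                raise KeyError(f"unknown probe set {ps!r}")
        gi = len(group_lists)
        group_lists.append(members)
        for ps in members:
            member_of[ps] = gi

    merged_ids: list[str] = []
    merge_map: dict[str, str] = {}
    columns: list[list[str]] = []
    seen_groups: set[int] = set()
    for ps in ids:
        gi = member_of.get(ps)
        if gi is None:
            merged_ids.append(ps)
            merge_map[ps] = ps
            columns.append([ps])
        elif gi not in seen_groups:
            seen_groups.add(gi)
            node = min(group_lists[gi])
            merged_ids.append(node)
            columns.append(group_lists[gi])
            for member in group_lists[gi]:
                merge_map[member] = node

    k = len(merged_ids)
    # membership-weight matrix: row g averages over the group's members
    w = np.zeros((k, n))
    for gi, members in enumerate(columns):
        for ps in members:
            w[gi, network.index_of(ps)] = 1.0 / len(members)

    corr_filled = np.where(network.stored_corr, network.corr, 0.0)
    anti_filled = np.where(network.stored_anti, network.anti, 0.0)
    new_corr = w @ corr_filled @ w.T
    new_anti = w @ anti_filled @ w.T
    np.fill_diagonal(new_corr, 0.0)
    np.fill_diagonal(new_anti, 0.0)
    merged = CovariationNetwork(
        probe_set_ids=merged_ids,
        corr=new_corr,
        anti=new_anti,
        stored_corr=new_corr > 0,
        stored_anti=new_anti > 0,
        alpha=network.alpha,
        n_comparisons=network.n_comparisons,
    )
    return MergedNetwork(
        network=merged,
        merge_map=merge_map,
        size_reduction=100.0 * (1.0 - k / n),
    )


def mcl_cluster(
    network: CovariationNetwork,
    inflation: float = 2.0,
    prune_threshold: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> MclResult:
    """Markov clustering on the positive-correlation graph.

    Only CORR edges are used (negative correlations are not valid random-walk
    weights).  Self-loops are set to each node's maximum incident weight.
    Iterates expansion (M @ M), inflation (elementwise power, column
    renormalisation) and pruning (zeroing entries below ``prune_threshold``,
    renormalisation) until the elementwise change falls under ``tol``.
    Clusters are read from attractors (rows with positive diagonal); each
    node joins the attractor with the largest incoming flow, ties going to
    the lexicographically smallest attractor.  The pruning score is
    floor(100 * mean retained column mass at the pruning steps).
    """
    n = network.n_probe_sets
    if n == 0:
        raise ValueError("empty network")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    w = np.where(network.stored_corr, network.corr, 0.0).astype(float)
    if (w < 0).any():
        raise ValueError("negative edge weight")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    incident_max = w.max(axis=0)
    np.fill_diagonal(w, np.where(incident_max > 0, incident_max, 1.0))

    def colnorm(m: np.ndarray) -> np.ndarray:
        s = m.sum(axis=0)
        s[s == 0] = 1.0
        return m / s

    m = colnorm(w)
    retained: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prev = m
        m = m @ m  # expansion
        m = colnorm(np.power(m, inflation))  # inflation
        mass_before = m.sum(axis=0)
        m[m < prune_threshold] = 0.0  # pruning
        mass_after = m.sum(axis=0)
        retained.extend((mass_after / np.where(mass_before > 0, mass_before, 1.0)).tolist())
        m = colnorm(m)
        if np.abs(m - prev).max() < tol:
            break

    pruning_score = int(math.floor(100.0 * (np.mean(retained) if retained else 1.0)))
    diag = np.diag(m)
    attractors = np.nonzero(diag > 1e-9)[0]
    if attractors.size == 0:  # not converged to a doubly idempotent matrix
        attractors = np.array([int(np.argmax(diag))])
    ids = network.probe_set_ids
    order = sorted(attractors.tolist(), key=lambda i: ids[i])
    assignment: dict[int, list[str]] = {}
    sub = m[order, :]
    for j in range(n):
        col = sub[:, j]
        best = float(col.max())
        if best <= 0:
            target = j if j in order else order[0]
        else:
            target = order[int(np.argmax(col))]  # argmax takes the first = smallest id
        assignment.setdefault(target, []).append(ids[j])
    clusters = [set(v) for v in assignment.values()]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return MclResult(clusters, pruning_score, inflation, n_iter)


def cluster_reproducibility(
    result_a: MclResult, result_b: MclResult, k: int = 10
) -> float:
    """Weighted mean overlap of the k largest clusters of ``result_a`` in ``result_b``.

    Both clusterings are restricted to their shared universe.  Each of the k
    largest a-clusters is matched to the b-cluster with the largest overlap
    (ties: larger b-cluster, then lexicographically smallest); its
    reproducibility is 100*|common|/sqrt(|ca|*|cb|) and the weighted mean
    uses weights 1/sqrt(|ca|*|cb|).
    """
    universe_a = set().union(*result_a.clusters) if result_a.clusters else set()
    universe_b = set().union(*result_b.clusters) if result_b.clusters else set()
    shared = universe_a & universe_b
    ca = [c & shared for c in result_a.clusters]
    cb = [c & shared for c in result_b.clusters]
    ca = [c for c in ca if c]
    cb = [c for c in cb if c]
    if not ca or not cb:
        raise ValueError("need at least one non-empty cluster on the shared universe")
    ca.sort(key=lambda c: (-len(c), min(c)))
    if k > len(ca):
        logger.warning("only %d clusters available; capping k=%d", len(ca), k)
        k = len(ca)
    num = 0.0
    den = 0.0
    for c in ca[:k]:
        # tie-break: most overlap, then larger b-cluster, then lexicographic
        candidates = sorted(
            cb, key=lambda d: (-len(c & d), -len(d), sorted(d))
        )
        best = candidates[0]
        gm = math.sqrt(len(c) * len(best))
        num += (100.0 * len(c & best) / gm) / gm
        den += 1.0 / gm
    return num / den


def rank_normalize(signals: pd.DataFrame) -> pd.DataFrame:
    """Replace raw signals by per-condition ranks on a 0-100 scale.

    Rows are biological conditions, columns probe sets.  Average ranks are
    used for ties; ranks r in [1, n] map to 100*(r-1)/(n-1).
    """
    n = signals.shape[1]
    if n < 2:
        raise ValueError("need at least 2 probe sets per condition to rank")
    ranks = np.apply_along_axis(rankdata, 1, signals.to_numpy(dtype=float))
    scaled = 100.0 * (ranks - 1.0) / (n - 1.0)
    return pd.DataFrame(scaled, index=signals.index, columns=signals.columns)


def rank_diff_cdfs(
    ranks: pd.DataFrame,
    pairs_by_class: Mapping[object, Sequence[tuple[str, str]]],
    n_random: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class mean CDF of absolute rank differences, on the grid 0..100.

    For each pair, the empirical CDF of |rank1 - rank2| over conditions is
    evaluated at the integers 0..100; classes report the pointwise mean over
    their pairs.  A "random" reference class of uniformly sampled probe-set
    pairs (seeded) is appended.
    """
    grid = np.arange(101)
    columns = {}

    def mean_cdf(pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        a = ranks[[p[0] for p in pairs]].to_numpy(dtype=float)
        b = ranks[[p[1] for p in pairs]].to_numpy(dtype=float)
        diffs = np.abs(a - b)  # conditions x pairs
        # CDF per pair then pointwise mean over pairs
        cdfs = (diffs[:, :, None] <= grid[None, None, :]).mean(axis=0)
        return cdfs.mean(axis=0)

    for cls, pairs in pairs_by_class.items():
        if len(pairs) == 0:
            logger.warning("class %r empty; omitted from rank-difference CDFs", cls)
            continue
        columns[cls] = mean_cdf(pairs)

    rng = np.random.default_rng(seed)
    cols = list(ranks.columns)
    if len(cols) >= 2 and n_random > 0:
        idx = rng.integers(0, len(cols), size=(n_random, 2))
        idx = idx[idx[:, 0] != idx[:, 1]]
        random_pairs = [(cols[i], cols[j]) for i, j in idx]
        if random_pairs:
            columns["random"] = mean_cdf(random_pairs)
    if not columns:
        raise ValueError("no class with pairs")
    return pd.DataFrame(columns, index=pd.Index(grid, name="abs_rank_diff"))
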