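"""Model/Results facade over the full similarity pipeline.

`ProbeSetSimilarity` is constructed from a `Dataset` (call matrices, target
annotation, signals); `fit()` builds one covariation network per call
matrix against its own empirical null, computes per-network corr/anti and
neighbourhood-overlap values for every alternative probe-set pair, calibrates
the three similarity limits on the pairs positively correlated in all
networks, applies the three-condition test, derives the 0/1/25/50/75/100
similarity classes and groups similar probe sets per class.  The returned
`SimilarityResults` carries the limits, the per-pair table, the networks and
diagnostics, and offers the downstream analyses (rank differences,
per-comparison statistics, merging + Markov clustering) as methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotation, grouping, io, netclust
from ._util import spawn_seeds
from .biclustering import assign_all
from .comparisons import comparison_pair_stats
from .covariation import CovariationNetwork, build_network, build_null
from .neighbourhood import pair_overlap
from .similarity import (
    PairSimilarity,
    SimilarityLimits,
    calibrate_limits,
    similarity_class,
    test_pair_in_network,
)
from .synthetic import Dataset

logger = logging.getLogger(__name__)


class ProbeSetSimilarity:
    """Similarity of alternative probe sets across covariation networks.

    Parameters
    ----------
    dataset : Dataset
        Call matrices (one per network), the probe-target annotation table
        and (optionally used) raw signals.
    alpha : float
        Significance level of the empirical-null filter for network edges.
    probe_limit : int
        Minimal number of targeting probes for a probe set to count as
        targeting a gene (bipartite adjacency limit).
    null_samples : int
        Random probe-set pairs per network for the empirical null.
    calibration_single_gene : bool
        Restrict calibration pairs to pairs whose members each target exactly
        one gene (removes cross-hybridisation ambiguity).
    """

    def __init__(
        self,
        dataset: Dataset,
        alpha: float = 0.05,
        probe_limit: int = 7,
        null_samples: int = 2000,
        calibration_single_gene: bool = True,
    ):
        if not dataset.call_matrices:
            raise ValueError("dataset has no call matrices")
        self.dataset = dataset
        self.alpha = alpha
        self.probe_limit = probe_limit
        self.null_samples = null_samples
        self.calibration_single_gene = calibration_single_gene

    def fit(self, seed: int = 0) -> "SimilarityResults":
        ds = self.dataset
        n_networks = len(ds.call_matrices)
        seeds = spawn_seeds(seed, n_networks)

        logger.info("building %d networks (alpha=%g)", n_networks, self.alpha)
        networks: list[CovariationNetwork] = []
        for calls, s in zip(ds.call_matrices, seeds):
            null = build_null(calls, self.null_samples, s)
            networks.append(build_network(calls, null, self.alpha))

        assignments = assign_all(ds.targets)
        by_gene: dict[str, list[str]] = {}
        universe = set(ds.call_matrices[0].probe_set_ids)
        for ps, g in assignments.items():
            if ps in universe:
                by_gene.setdefault(g, []).append(ps)
        alt_pairs: list[tuple[str, str, str]] = []  # (ps_a, ps_b, gene)
        for g, members in sorted(by_gene.items()):
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    alt_pairs.append((members[i], members[j], g))
        logger.info("%d alternative pairs over %d genes",
                    len(alt_pairs), sum(1 for m in by_gene.values() if len(m) > 1))

        # per-network pair values; absent values enter as 0 (corr, anti)
        # and 0.0 (overlap log10 p, i.e. p = 1)
        corr = np.zeros((len(alt_pairs), n_networks))
        anti = np.zeros((len(alt_pairs), n_networks))
        overlap = np.zeros((len(alt_pairs), n_networks))
        positive = np.zeros((len(alt_pairs), n_networks), dtype=bool)
        for k, net in enumerate(networks):
            for p, (a, b, _gene) in enumerate(alt_pairs):
                c, x = net.pair_values(a, b)
                corr[p, k] = c
                anti[p, k] = x
                positive[p, k] = net.has_positive_edge(a, b)
                ov = pair_overlap(net, a, b)
                overlap[p, k] = ov.log10_p

        always_positive = positive.all(axis=1)
        calib_mask = always_positive.copy()
        if self.calibration_single_gene:
            single = np.array([
                len(ds.targets.genes_of(a)) == 1 and len(ds.targets.genes_of(b)) == 1
                for a, b, _ in alt_pairs
            ])
            calib_mask &= single
        n_calib = int(calib_mask.sum())
        logger.info("calibration set: %d pairs positive in all %d networks",
                    n_calib, n_networks)
        limits = calibrate_limits(
            corr[calib_mask].ravel(),
            anti[calib_mask].ravel(),
            overlap[calib_mask].ravel(),
            n_networks=n_networks,
            n_calibration_pairs=n_calib,
        )

        pairs: list[PairSimilarity] = []
        for p, (a, b, gene) in enumerate(alt_pairs):
            per_network = [
                test_pair_in_network(corr[p, k], anti[p, k], overlap[p, k], limits)
                for k in range(n_networks)
            ]
            n_similar = sum(per_network)
            pairs.append(PairSimilarity(
                pair=(a, b),
                gene=gene,
                per_network=per_network,
                n_similar=n_similar,
                similarity_class=similarity_class(n_similar, n_networks),
                mean_corr=float(corr[p].mean()),
                mean_anti=float(anti[p].mean()),
                mean_overlap=float(overlap[p].mean()),
            ))

        groups_by_class = {}
        pivots_by_class = {}
        for cls in (1, 25, 50, 75, 100):
            similar = [p.pair for p in pairs if p.similarity_class >= cls]
            tris = grouping.find_triangles(similar)
            groups_by_class[cls], pivots_by_class[cls] = grouping.aggregate_groups(
                tris, similar
            )

        return SimilarityResults(
            model=self,
            networks=networks,
            limits=limits,
            pairs=pairs,
            assignments=assignments,
            groups_by_class=groups_by_class,
            pivots_by_class=pivots_by_class,
            seed=seed,
        )


@dataclass
class SimilarityResults:
    """Fitted similarity limits, per-pair classes and derived groupings."""

    model: ProbeSetSimilarity
    networks: list[CovariationNetwork]
    limits: SimilarityLimits
    pairs: list[PairSimilarity]
    assignments: dict[str, str]
    groups_by_class: dict[int, list[grouping.ProbeSetGroup]]
    pivots_by_class: dict[int, list[grouping.PivotRecord]]
    seed: int

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def class_of(self) -> dict[tuple[str, str], int]:
        return {p.pair: p.similarity_class for p in self.pairs}

    def pairs_by_class(self) -> dict[int, list[tuple[str, str]]]:
        out: dict[int, list[tuple[str, str]]] = {}
        for p in self.pairs:
            out.setdefault(p.similarity_class, []).append(p.pair)
        return out

    def class_distribution(self) -> pd.Series:
        """Percentage of alternative pairs per similarity class."""
        counts = pd.Series(
            [p.similarity_class for p in self.pairs], dtype=int
        ).value_counts()
        idx = [0, 1, 25, 50, 75, 100]
        counts = counts.reindex(idx, fill_value=0)
        return 100.0 * counts / max(len(self.pairs), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "probe_set_1": p.pair[0],
                "probe_set_2": p.pair[1],
                "gene": p.gene,
                "similarity_class": p.similarity_class,
                "n_networks_similar": p.n_similar,
                "mean_corr": p.mean_corr,
                "mean_anti": p.mean_anti,
                "mean_overlap": p.mean_overlap,
            }
            for p in self.pairs
        ])

    # --- downstream analyses ------------------------------------------

    def rank_diff_cdfs(self, n_random: int = 1000) -> pd.DataFrame:
        ranks = netclust.rank_normalize(self.model.dataset.signals)
        return netclust.rank_diff_cdfs(
            ranks, self.pairs_by_class(), n_random=n_random, seed=self.seed
        )

    def comparison_stats(self, network_index: int = 0):
        calls = self.model.dataset.call_matrices[network_index]
        return comparison_pair_stats(calls, self.pairs_by_class())

    def localisation_by_class(self, min_probes: int = 11) -> pd.DataFrame:
        return annotation.scores_by_similarity(
            self.pairs, self.model.dataset.targets, min_probes=min_probes
        )

    def merge_and_cluster(
        self,
        min_class: int = 50,
        network_index: int = 0,
        inflation: float = 2.0,
        prune_threshold: float = 1e-4,
    ) -> tuple[netclust.MergedNetwork, netclust.MclResult]:
        """Merge groups of similarity >= ``min_class`` and MCL-cluster."""
        groups = self.groups_by_class[min_class]
        pivots = {pv.probe_set for pv in self.pivots_by_class[min_class]}
        taken: set[str] = set()
        disjoint = []
        for g in groups:
            members = frozenset(g.members - pivots - taken)
            if len(members) >= 2:
                disjoint.append(grouping.ProbeSetGroup(members, frozenset(), ()))
                taken |= members
        merged = netclust.merge_probe_sets(self.networks[network_index], disjoint)
        result = netclust.mcl_cluster(
            merged.network, inflation=inflation, prune_threshold=prune_threshold
        )
        return merged, result

    def write_tables(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_similarity_table(self.pairs, out / "pair_similarity.tsv")
        c5, a95, o95 = (self.limits.corr_5th, self.limits.anti_95th,
                        self.limits.overlap_95th)
        pd.DataFrame([{
            "n_networks": self.n_networks,
            "probe_limit": self.model.probe_limit,
            "n_calibration_pairs": self.limits.n_calibration_pairs,
            "corr_5th": c5, "anti_95th": a95, "overlap_95th": o95,
        }]).to_csv(out / "limits.tsv", sep="\t", index=False)
        rows = []
        for cls, groups in self.groups_by_class.items():
            for gi, g in enumerate(groups):
                rows.append({
                    "class": cls,
                    "group_id": f"c{cls}_g{gi + 1}",
                    "members": ";".join(sorted(g.members)),
                    "bad_links": ";".join(f"{a}|{b}" for a, b in sorted(g.bad_links)),
                })
        pd.DataFrame(rows, columns=["class", "group_id", "members", "bad_links"]).to_csv(
            out / "groups.tsv", sep="\t", index=False
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        dist = self.class_distribution()
        c5, a95, o95 = self.limits.rounded()
        lines = [
            "Probe-set similarity from covariation networks",
            "=" * 52,
            f"networks:            {self.n_networks}",
            f"probe sets:          {self.networks[0].n_probe_sets}",
            f"alternative pairs:   {len(self.pairs)}",
            f"calibration pairs:   {self.limits.n_calibration_pairs}",
            f"edge significance:   alpha = {self.model.alpha:g}",
            "",
            "similarity test limits (calibrated)",
            f"  corr_5th    >= {c5:6d}   (unrounded {self.limits.corr_5th:.2f})",
            f"  anti_95th   <= {a95:6d}   (unrounded {self.limits.anti_95th:.2f})",
            f"  overlap_95th<= {o95:6d}   (log10 p, unrounded {self.limits.overlap_95th:.2f})",
            "",
            "similarity class distribution (% of alternative pairs)",
        ]
        for cls in (0, 1, 25, 50, 75, 100):
            lines.append(f"  {cls:>3}%: {dist[cls]:6.1f}")
        lines.append("")
        for cls in (100, 50):
            lines.append(
                f"groups at class >= {cls}%: {len(self.groups_by_class[cls])} "
                f"(pivots: {len(self.pivots_by_class[cls])})"
            )
        return "\n".join(lines)

    def plot_rank_cdfs(self, ax=None):
        """Plot per-class mean rank-difference CDFs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        cdfs = self.rank_diff_cdfs()
        if ax is None:
            _, ax = plt.subplots()
        for col in cdfs.columns:
            ax.plot(cdfs.index, cdfs[col], label=str(col))
        ax.set_xlabel("absolute rank difference")
        ax.set_ylabel("mean CDF")
        ax.legend(title="similarity class")
        return ax
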