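"""Merging, Markov clustering, reproducibility and rank analysis."""

import numpy as np
import pandas as pd
import pytest

from probesim import (
    cluster_reproducibility,
    mcl_cluster,
    merge_probe_sets,
    rank_diff_cdfs,
    rank_normalize,
)
from probesim.grouping import ProbeSetGroup
from probesim.netclust import MclResult

from conftest import make_network


def group(*members):
    return ProbeSetGroup(frozenset(members), frozenset(), ())


class TestMergeProbeSets:
    def test_merged_corr_is_member_mean(self):
        net = make_network(
            ["A", "B", "X"],
            corr_edges=[("A", "X", 40.0), ("B", "X", 60.0)],
        )
        merged = merge_probe_sets(net, [group("A", "B")])
        m = merged.network
        assert m.probe_set_ids == ["A", "X"]
        assert m.corr[m.index_of("A"), m.index_of("X")] == pytest.approx(50.0)

    def test_absent_entries_count_as_zero(self):
        net = make_network(["A", "B", "X"], corr_edges=[("A", "X", 40.0)])
        merged = merge_probe_sets(net, [group("A", "B")])
        m = merged.network
        assert m.corr[m.index_of("A"), m.index_of("X")] == pytest.approx(20.0)

    def test_node_count_reduction(self):
        ids = [f"p{i}" for i in range(100)]
        net = make_network(ids, corr_edges=[])
        groups = [group(f"p{2 * i}", f"p{2 * i + 1}") for i in range(10)]
        merged = merge_probe_sets(net, groups)
        assert merged.network.n_probe_sets == 90
        assert merged.size_reduction == pytest.approx(10.0)

    def test_intra_group_edges_dropped(self):
        net = make_network(["A", "B"], corr_edges=[("A", "B", 80.0)])
        merged = merge_probe_sets(net, [group("A", "B")])
        assert merged.network.n_probe_sets == 1
        assert merged.network.corr[0, 0] == 0.0

    def test_overlapping_groups_rejected(self):
        net = make_network(["A", "B", "C"], corr_edges=[])
        with pytest.raises(ValueError):
            merge_probe_sets(net, [group("A", "B"), group("B", "C")])


class TestMcl:
    def _two_cliques(self):
        ids = list("abcdef")
        edges = []
        for grp in (("a", "b", "c"), ("d", "e", "f")):
            for i, x in enumerate(grp):
                for y in grp[i + 1:]:
                    edges.append((x, y, 50.0))
        return make_network(ids, corr_edges=edges)

    def test_disconnected_cliques_recovered(self):
        result = mcl_cluster(self._two_cliques())
        assert sorted(map(sorted, result.clusters)) == [
            ["a", "b", "c"], ["d", "e", "f"]
        ]

    def test_single_node(self):
        result = mcl_cluster(make_network(["only"], corr_edges=[]))
        assert result.clusters == [{"only"}]

    def test_no_pruning_gives_perfect_score(self):
        result = mcl_cluster(self._two_cliques(), prune_threshold=0.0)
        assert result.pruning_score == 100

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(make_network([], corr_edges=[]))

    def test_clusters_partition_universe(self):
        rng = np.random.default_rng(4)
        ids = [f"n{i}" for i in range(20)]
        edges = [
            (ids[i], ids[j], float(rng.uniform(10, 90)))
            for i in range(20) for j in range(i + 1, 20)
            if rng.random() < 0.2
        ]
        result = mcl_cluster(make_network(ids, corr_edges=edges))
        members = sorted(x for c in result.clusters for x in c)
        assert members == sorted(ids)


class TestClusterReproducibility:
    def test_identical_clusterings(self):
        r = MclResult([set("abcd"), set("ef")], 100, 2.0, 3)
        assert cluster_reproducibility(r, r) == pytest.approx(100.0)

    def test_geometric_mean_fixture(self):
        # largest a-cluster (9) matched to a 16-cluster sharing 6 members:
        # rep = 100 * 6 / sqrt(9*16) = 50
        xs = [f"x{i}" for i in range(9)]
        ys = [f"y{i}" for i in range(16)]
        a = MclResult([set(xs)] + [{y} for y in ys], 100, 2.0, 3)
        b = MclResult(
            [set(xs[:6] + ys[:10]), set(xs[6:] + ys[10:])], 100, 2.0, 3
        )
        assert cluster_reproducibility(a, b, k=1) == pytest.approx(50.0)

    def test_disjoint_clusterings(self):
        shared = list("abcdef")
        a = MclResult([set(shared[:3]), set(shared[3:])], 100, 2.0, 3)
        b = MclResult([{shared[0], shared[3]}, {shared[1], shared[4]},
                       {shared[2], shared[5]}], 100, 2.0, 3)
        # every a-cluster overlaps any b-cluster in exactly 1 member
        assert cluster_reproducibility(a, b) < 60.0

    def test_roughly_symmetric_on_balanced_fixture(self):
        rng = np.random.default_rng(6)
        universe = [f"u{i}" for i in range(40)]
        a = MclResult([set(universe[:20]), set(universe[20:])], 100, 2.0, 3)
        perm = list(universe)
        rng.shuffle(perm)
        b = MclResult([set(perm[:20]), set(perm[20:])], 100, 2.0, 3)
        assert abs(cluster_reproducibility(a, b) - cluster_reproducibility(b, a)) < 10


class TestRankNormalize:
    def test_extremes_map_to_0_and_100(self):
        df = pd.DataFrame([[3.0, 1.0, 2.0]], columns=list("abc"))
        ranks = rank_normalize(df)
        assert ranks.iloc[0].tolist() == [100.0, 0.0, 50.0]

    def test_five_distinct_values(self):
        df = pd.DataFrame([[10, 20, 30, 40, 50]], columns=list("abcde"))
        assert rank_normalize(df).iloc[0].tolist() == [0, 25, 50, 75, 100]

    def test_average_ties(self):
        df = pd.DataFrame([[1.0, 1.0, 2.0]], columns=list("abc"))
        assert rank_normalize(df).iloc[0].tolist() == [25.0, 25.0, 100.0]

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            rank_normalize(pd.DataFrame([[1.0]], columns=["a"]))


class TestRankDiffCdfs:
    def test_identical_signals_have_cdf_one_at_zero(self):
        rng = np.random.default_rng(2)
        sig = rng.uniform(1, 100, size=(20, 4))
        sig[:, 1] = sig[:, 0]
        ranks = rank_normalize(pd.DataFrame(sig, columns=list("abcd")))
        cdfs = rank_diff_cdfs(ranks, {"k": [("a", "b")]}, n_random=0)
        assert cdfs["k"].iloc[0] == pytest.approx(1.0)

    def test_mean_of_two_pairs(self):
        rng = np.random.default_rng(3)
        ranks = rank_normalize(
            pd.DataFrame(rng.uniform(size=(15, 6)), columns=list("abcdef"))
        )
        c1 = rank_diff_cdfs(ranks, {"k": [("a", "b")]}, n_random=0)["k"]
        c2 = rank_diff_cdfs(ranks, {"k": [("c", "d")]}, n_random=0)["k"]
        both = rank_diff_cdfs(ranks, {"k": [("a", "b"), ("c", "d")]}, n_random=0)["k"]
        assert np.allclose(both, (c1 + c2) / 2)

    def test_cdfs_monotone_reaching_one(self):
        rng = np.random.default_rng(9)
        ranks = rank_normalize(
            pd.DataFrame(rng.uniform(size=(30, 8)),
                         columns=[f"p{i}" for i in range(8)])
        )
        cdfs = rank_diff_cdfs(
            ranks, {"k": [("p0", "p1"), ("p2", "p3")]}, n_random=50, seed=1
        )
        for col in cdfs.columns:
            vals = cdfs[col].to_numpy()
            assert (np.diff(vals) >= -1e-12).all()
            assert vals[-1] == pytest.approx(1.0)
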