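"""Bicluster extraction, classification and gene assignment."""

import networkx as nx
import numpy as np
import pytest

from probesim import (
    TargetRecord,
    TargetTable,
    assign_gene,
    build_adjacency,
    classify_bicluster,
    extract_bicluster,
    partition_chip,
)
from probesim.biclustering import Adjacency, Bicluster


def record(ps, gene, exon=11, intron=0, up=0, down=0, source="Ensembl",
           transcripts=("t1",), last=0):
    return TargetRecord(
        probe_set=ps, gene=gene, source=source,
        probes_exon=exon, probes_intron=intron, probes_up=up, probes_down=down,
        transcripts_targeted=frozenset(transcripts),
        transcripts_untargeted=frozenset(),
        exons_targeted=frozenset({1}),
        probes_last_exon=last,
    )


def adjacency_from_edges(edges):
    ps_to_genes, gene_to_ps = {}, {}
    for ps, g in edges:
        ps_to_genes.setdefault(ps, set()).add(g)
        gene_to_ps.setdefault(g, set()).add(ps)
    return Adjacency(ps_to_genes, gene_to_ps, limit=1)


def random_adjacency(rng, max_ps=12, max_genes=8, p=0.25):
    n_ps = rng.integers(1, max_ps + 1)
    n_g = rng.integers(1, max_genes + 1)
    edges = [
        (f"ps{i}", f"g{j}")
        for i in range(n_ps)
        for j in range(n_g)
        if rng.random() < p
    ]
    return adjacency_from_edges(edges) if edges else None


class TestBuildAdjacency:
    def test_probe_limit_threshold(self):
        targets = TargetTable([
            record("ps1", "A", exon=8),
            record("ps2", "A", exon=4, intron=2),  # 6 total
        ])
        adj = build_adjacency(targets, limit=7)
        assert adj.ps_to_genes == {"ps1": {"A"}}
        assert "ps2" not in adj.probe_sets  # dropped from the universe

    def test_total_probes_sums_all_categories(self):
        targets = TargetTable([record("ps1", "A", exon=2, intron=2, up=2, down=1)])
        assert build_adjacency(targets, limit=7).n_edges() == 1

    def test_raising_limit_never_adds_cells(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            records = [
                record(f"ps{i}", f"g{j}", exon=int(rng.integers(0, 12)))
                for i in range(6) for j in range(4)
                if rng.random() < 0.5
            ]
            if not records:
                continue
            targets = TargetTable(records)
            prev = None
            for limit in range(1, 8):
                edges = {
                    (p, g)
                    for p, gs in build_adjacency(targets, limit).ps_to_genes.items()
                    for g in gs
                }
                if prev is not None:
                    assert edges <= prev
                prev = edges


class TestExtractBicluster:
    def test_isolated_single_pair(self):
        adj = adjacency_from_edges([("ps1", "A")])
        b = extract_bicluster("ps1", adj)
        assert (b.probe_sets, b.genes, b.depth) == ({"ps1"}, {"A"}, 1)
        assert b.class_label == "SS"

    def test_two_step_closure(self):
        adj = adjacency_from_edges(
            [("ps1", "A"), ("ps2", "A"), ("ps2", "B"), ("ps3", "B")]
        )
        b = extract_bicluster("ps1", adj)
        assert b.probe_sets == {"ps1", "ps2", "ps3"}
        assert b.genes == {"A", "B"}
        assert b.depth == 2
        assert b.density == pytest.approx(100 * 4 / 6)
        assert b.class_label == "CX"

    def test_chain_depth_three(self):
        adj = adjacency_from_edges([
            ("ps1", "A"), ("ps2", "A"), ("ps2", "B"), ("ps3", "B"),
            ("ps3", "C"), ("ps4", "C"),
        ])
        b = extract_bicluster("ps1", adj)
        assert len(b.probe_sets) == 4 and len(b.genes) == 3
        assert b.depth == 3
        assert b.class_label == "HX"

    def test_unknown_seed(self):
        with pytest.raises(KeyError):
            extract_bicluster("nope", adjacency_from_edges([("ps1", "A")]))

    def test_membership_seed_invariant_depth_not(self):
        adj = adjacency_from_edges([
            ("ps1", "A"), ("ps2", "A"), ("ps2", "B"), ("ps3", "B"),
        ])
        members = {
            (frozenset(extract_bicluster(seed, adj).probe_sets),
             frozenset(extract_bicluster(seed, adj).genes))
            for seed in ("ps1", "ps2", "ps3")
        }
        assert len(members) == 1
        assert extract_bicluster("ps2", adj).depth == 1  # centre seed
        assert extract_bicluster("ps1", adj).depth == 2


@pytest.mark.parametrize(
    "n_ps, n_genes, depth, expected",
    [
        (1, 1, 1, "SS"),
        (1, 3, 1, "SM"),
        (4, 1, 1, "MS"),
        (2, 2, 1, "MM"),
        (3, 2, 2, "CX"),
        (4, 3, 3, "HX"),
        (5, 4, 5, "HX"),
    ],
)
def test_classify_bicluster(n_ps, n_genes, depth, expected):
    b = Bicluster(
        probe_sets={f"p{i}" for i in range(n_ps)},
        genes={f"g{i}" for i in range(n_genes)},
        depth=depth, density=100.0, class_label="", seed="p0",
    )
    assert classify_bicluster(b) == expected


class TestPartitionChip:
    def test_two_disconnected_ss(self):
        adj = adjacency_from_edges([("ps1", "A"), ("ps2", "B")])
        bics, summary = partition_chip(adj)
        assert len(bics) == 2
        assert all(b.class_label == "SS" for b in bics)
        assert summary.set_index("class").loc["SS", "n_biclusters"] == 2

    def test_component_equals_closure(self):
        adj = adjacency_from_edges(
            [("ps1", "A"), ("ps2", "A"), ("ps2", "B"), ("ps3", "B")]
        )
        bics, _ = partition_chip(adj)
        assert len(bics) == 1
        assert bics[0].probe_sets == {"ps1", "ps2", "ps3"}

    def test_partition_covers_universe_disjointly(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            adj = random_adjacency(rng)
            if adj is None:
                continue
            bics, _ = partition_chip(adj)
            seen = []
            for b in bics:
                seen.extend(b.probe_sets)
            assert sorted(seen) == sorted(adj.probe_sets)

    def test_matches_networkx_components(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            adj = random_adjacency(rng)
            if adj is None:
                continue
            g = nx.Graph()
            for ps, genes in adj.ps_to_genes.items():
                for gene in genes:
                    g.add_edge(("ps", ps), ("gene", gene))
            expected = {
                frozenset(n for kind, n in comp if kind == "ps")
                for comp in nx.connected_components(g)
            }
            got = {frozenset(b.probe_sets) for b in partition_chip(adj)[0]}
            assert got == expected

    def test_class_uses_min_depth_over_seeds(self):
        adj = adjacency_from_edges([
            ("ps1", "A"), ("ps2", "A"), ("ps2", "B"), ("ps3", "B"),
        ])
        bics, _ = partition_chip(adj)
        # ps2 reaches everything in one step -> depth 1 -> MM, not CX
        assert bics[0].depth == 1
        assert bics[0].class_label == "MM"
        assert bics[0].depth == min(
            extract_bicluster(s, adj).depth for s in ("ps1", "ps2", "ps3")
        )


class TestAssignGene:
    def test_highest_probe_count_wins(self):
        targets = TargetTable([
            record("ps1", "X", exon=9),
            record("ps1", "Y", exon=5),
        ])
        assert assign_gene("ps1", targets) == "X"

    def test_target_type_breaks_probe_tie(self):
        targets = TargetTable([
            record("ps1", "X", exon=8, intron=0),
            record("ps1", "Y", exon=0, intron=8),
        ])
        assert assign_gene("ps1", targets) == "X"

    def test_gene_source_breaks_deep_tie(self):
        targets = TargetTable([
            record("ps1", "X", exon=8, source="Ensembl"),
            record("ps1", "Y", exon=8, source="AceView"),
        ])
        assert assign_gene("ps1", targets) == "X"

    def test_alphabetic_last_resort(self):
        targets = TargetTable([
            record("ps1", "GeneB", exon=8),
            record("ps1", "GeneA", exon=8),
        ])
        assert assign_gene("ps1", targets) == "GeneA"

    def test_transcript_group_ratio(self):
        # gene X: two probe sets in one transcript group -> ratio 2/1 = 2
        # gene Y: two probe sets in two groups -> ratio 2/2 = 1
        targets = TargetTable([
            record("ps1", "X", exon=8, transcripts=("t1",)),
            record("ps2", "X", exon=8, transcripts=("t1",)),
            record("ps1", "Y", exon=8, transcripts=("u1",)),
            record("ps3", "Y", exon=8, transcripts=("u2",)),
        ])
        assert assign_gene("ps1", targets) == "X"

    def test_no_gene_errors(self):
        targets = TargetTable([record("ps1", "X")])
        with pytest.raises(KeyError):
            assign_gene("ps2", targets)
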