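"""Probe-set x gene biclusters and single-gene assignment.

The targeting relation between probe sets and genes is a bipartite adjacency:
cell (i, j) is set when probe set i places at least `probe number limit`
probes in gene j (default limit 7, which balances specificity against
sensitivity).  Biclusters are the connected components of this bipartite
graph, found by an alternating recursive closure from a seed probe set; the
recursion depth needed to exhaust a component, together with its shape,
yields six classes:

  SS  single probe set, single gene        (depth 1)
  SM  single probe set, multiple genes     (depth 1)
  MS  multiple probe sets, single gene     (depth 1)
  MM  multiple x multiple, depth 1
  CX  multiple x multiple, depth 2 ("complex")
  HX  multiple x multiple, depth >= 3 ("hyper-complex")

Each probe set is also assigned to exactly one gene by a six-step tie-break
cascade (probe count, target type, probe-set/transcript-group ratio, probe-set
count, gene source, alphabetic order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

GENE_SOURCES = ("Ensembl", "AceView", "GOP")
_SOURCE_RANK = {s: i for i, s in enumerate(GENE_SOURCES)}
# target-type categories in decreasing quality: probes in exons beat probes in
# introns, which beat probes just upstream, then downstream of the gene
TARGET_CATEGORIES = ("probes_exon", "probes_intron", "probes_up", "probes_down")


@dataclass(frozen=True)
class TargetRecord:
    """One (probe set, gene) targeting relation from the annotation table."""

    probe_set: str
    gene: str
    source: str
    probes_exon: int
    probes_intron: int
    probes_up: int
    probes_down: int
    transcripts_targeted: frozenset[str]
    transcripts_untargeted: frozenset[str]
    exons_targeted: frozenset[int]
    probes_last_exon: int

    def __post_init__(self) -> None:
        if self.source not in GENE_SOURCES:
            raise ValueError(
                f"unknown gene source {self.source!r}; allowed: {', '.join(GENE_SOURCES)}"
            )
        for name in (*TARGET_CATEGORIES, "probes_last_exon"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}={getattr(self, name)}")

    @property
    def total_probes(self) -> int:
        """Total targeting probes = exon + intron + upstream + downstream."""
        return self.probes_exon + self.probes_intron + self.probes_up + self.probes_down


class TargetTable:
    """Collection of TargetRecords indexed by probe set and by gene."""

    def __init__(self, records: Iterable[TargetRecord]):
        self.records: list[TargetRecord] = list(records)
        seen = set()
        self.by_probe_set: dict[str, dict[str, TargetRecord]] = {}
        self.by_gene: dict[str, dict[str, TargetRecord]] = {}
        for r in self.records:
            key = (r.probe_set, r.gene)
            if key in seen:
                raise ValueError(f"duplicate (probe_set, gene) record {key}")
            seen.add(key)
            self.by_probe_set.setdefault(r.probe_set, {})[r.gene] = r
            self.by_gene.setdefault(r.gene, {})[r.probe_set] = r

    def __len__(self) -> int:
        return len(self.records)

    def record(self, probe_set: str, gene: str) -> TargetRecord:
        try:
            return self.by_probe_set[probe_set][gene]
        except KeyError:
            raise KeyError(f"no record for ({probe_set!r}, {gene!r})") from None

    def genes_of(self, probe_set: str) -> set[str]:
        return set(self.by_probe_set.get(probe_set, ()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "probe_set": r.probe_set,
                "gene": r.gene,
                "source": r.source,
                "probes_exon": r.probes_exon,
                "probes_intron": r.probes_intron,
                "probes_up": r.probes_up,
                "probes_down": r.probes_down,
                "transcripts_targeted": ";".join(sorted(r.transcripts_targeted)),
                "transcripts_untargeted": ";".join(sorted(r.transcripts_untargeted)),
                "exons_targeted": ";".join(str(e) for e in sorted(r.exons_targeted)),
                "probes_last_exon": r.probes_last_exon,
            })
        return pd.DataFrame(rows)


@dataclass
class Adjacency:
    """Bipartite probe-set/gene adjacency at a given probe-number limit."""

    ps_to_genes: dict[str, set[str]]
    gene_to_ps: dict[str, set[str]]
    limit: int

    @property
    def probe_sets(self) -> set[str]:
        return set(self.ps_to_genes)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_ps)

    def n_edges(self) -> int:
        return sum(len(g) for g in self.ps_to_genes.values())


@dataclass
class Bicluster:
    probe_sets: set[str]
    genes: set[str]
    depth: int
    density: float  # percent of filled cells
    class_label: str
    seed: str


def build_adjacency(targets: TargetTable, limit: int = 7) -> Adjacency:
    """Keep (probe set, gene) cells with >= ``limit`` targeting probes.

    Probe sets and genes left without any cell drop out of the bipartite
    universe.
    """
    if limit < 1:
        raise ValueError("probe number limit must be >= 1")
    ps_to_genes: dict[str, set[str]] = {}
    gene_to_ps: dict[str, set[str]] = {}
    for r in targets.records:
        if r.total_probes >= limit:
            ps_to_genes.setdefault(r.probe_set, set()).add(r.gene)
            gene_to_ps.setdefault(r.gene, set()).add(r.probe_set)
    return Adjacency(ps_to_genes, gene_to_ps, limit)


def _closure_depth(seed: str, adj: Adjacency) -> tuple[set[str], set[str], int]:
    """Alternating closure from a seed probe set; returns (ps, genes, depth).

    Depth 1 adds the seed's genes and all probe sets targeting them; each
    further depth adds genes newly targeted by the previous depth's probe
    sets and the probe sets targeting those new genes.  Depth is the last
    level at which anything new appeared.
    """
    ps_members = {seed}
    gene_members: set[str] = set()
    frontier_ps = {seed}
    depth = 0
    level = 0
    while True:
        level += 1
        new_genes = set()
        for ps in frontier_ps:
            new_genes |= adj.ps_to_genes[ps] - gene_members
        new_ps = set()
        for g in new_genes:
            new_ps |= adj.gene_to_ps[g] - ps_members
        if not new_genes and not new_ps:
            break
        gene_members |= new_genes
        ps_members |= new_ps
        frontier_ps = new_ps
        depth = level
        if not new_ps:
            break
    return ps_members, gene_members, max(depth, 1)


def _density(ps: set[str], genes: set[str], adj: Adjacency) -> float:
    filled = sum(len(adj.ps_to_genes[p] & genes) for p in ps)
    return 100.0 * filled / (len(ps) * len(genes))


def extract_bicluster(seed: str, adj: Adjacency) -> Bicluster:
    """Bicluster reachable from ``seed`` by the alternating closure."""
    if seed not in adj.ps_to_genes:
        raise KeyError(f"unknown seed probe set {seed!r}")
    ps, genes, depth = _closure_depth(seed, adj)
    b = Bicluster(ps, genes, depth, _density(ps, genes, adj), "", seed)
    b.class_label = classify_bicluster(b)
    return b


def classify_bicluster(b: Bicluster) -> str:
    """SS/SM/MS for single-sided components; MM/CX/HX split by depth 1/2/>=3."""
    n_ps, n_genes = len(b.probe_sets), len(b.genes)
    if n_ps == 1 and n_genes == 1:
        return "SS"
    if n_ps == 1:
        return "SM"
    if n_genes == 1:
        return "MS"
    if b.depth == 1:
        return "MM"
    if b.depth == 2:
        return "CX"
    return "HX"


def partition_chip(
    adj: Adjacency, targets: TargetTable | None = None
) -> tuple[list[Bicluster], pd.DataFrame]:
    """Partition the bipartite universe into biclusters (= components).

    A component's depth is the minimum closure depth over all of its probe-set
    seeds, making the class label independent of seed order.  The summary
    counts biclusters, probe sets and genes per class; when ``targets`` is
    given it also reports %R, the percentage of probe sets that are
    alternative (share their assigned gene with another probe set).
    """
    if not adj.ps_to_genes:
        raise ValueError("empty adjacency")
    biclusters: list[Bicluster] = []
    unseen = set(adj.ps_to_genes)
    for seed in sorted(adj.ps_to_genes):
        if seed not in unseen:
            continue
        ps, genes, _ = _closure_depth(seed, adj)
        depth = min(_closure_depth(p, adj)[2] for p in ps)
        b = Bicluster(ps, genes, depth, _density(ps, genes, adj), "", min(ps))
        b.class_label = classify_bicluster(b)
        biclusters.append(b)
        unseen -= ps

    rows = []
    for cls in ("SS", "SM", "MS", "MM", "CX", "HX"):
        of_cls = [b for b in biclusters if b.class_label == cls]
        rows.append({
            "class": cls,
            "n_biclusters": len(of_cls),
            "n_probe_sets": sum(len(b.probe_sets) for b in of_cls),
            "n_genes": sum(len(b.genes) for b in of_cls),
        })
    summary = pd.DataFrame(rows)
    if targets is not None:
        assignments = assign_all(targets, restrict_to=adj.probe_sets)
        gene_counts: dict[str, int] = {}
        for g in assignments.values():
            gene_counts[g] = gene_counts.get(g, 0) + 1
        n_alt = sum(1 for g in assignments.values() if gene_counts[g] > 1)
        summary.attrs["pct_alternative"] = 100.0 * n_alt / len(assignments)
    return biclusters, summary


def transcript_group_counts(targets: TargetTable) -> dict[str, int]:
    """Per gene: number of groups of probe sets with identical targeted-transcript sets."""
    out = {}
    for gene, recs in targets.by_gene.items():
        out[gene] = len({r.transcripts_targeted for r in recs.values()})
    return out


def assign_gene(
    ps: str,
    targets: TargetTable,
    groups_per_gene: Mapping[str, int] | None = None,
) -> str:
    """Assign a probe set to a single gene by the six-criterion cascade.

    Candidates are filtered successively by: (1) highest number of targeting
    probes; (2) best target type — compare the best non-empty category
    (exon > intron > upstream > downstream), then the probe count in it;
    (3) maximal ratio of targeting probe sets to transcript-groups of probe
    sets; (4) minimal number of targeting probe sets; (5) gene source
    (Ensembl > AceView > GOP); (6) first gene in alphabetic order.
    """
    genes = targets.genes_of(ps)
    if not genes:
        raise KeyError(f"probe set {ps!r} targets no gene")
    if groups_per_gene is None:
        groups_per_gene = transcript_group_counts(targets)
    candidates = sorted(genes)

    def best_category(rec: TargetRecord) -> tuple[int, int]:
        # (rank of best non-empty category, probe count in it); lower rank wins
        for rank, name in enumerate(TARGET_CATEGORIES):
            cnt = getattr(rec, name)
            if cnt > 0:
                return rank, cnt
        return len(TARGET_CATEGORIES), 0

    def filter_best(cands: list[str], key, maximize: bool) -> list[str]:
        vals = {g: key(g) for g in cands}
        best = max(vals.values()) if maximize else min(vals.values())
        return [g for g in cands if vals[g] == best]

    rec = lambda g: targets.record(ps, g)
    # 1. highest number of targeting probes
    candidates = filter_best(candidates, lambda g: rec(g).total_probes, True)
    # 2. best target type: better category first, then more probes in it
    candidates = filter_best(
        candidates,
        lambda g: (-best_category(rec(g))[0], best_category(rec(g))[1]),
        True,
    )
    # 3. maximal (#probe sets targeting g) / (#transcript groups of g)
    candidates = filter_best(
        candidates,
        lambda g: len(targets.by_gene[g]) / max(groups_per_gene.get(g, 1), 1),
        True,
    )
    # 4. minimal number of targeting probe sets
    candidates = filter_best(candidates, lambda g: len(targets.by_gene[g]), False)
    # 5. gene source: Ensembl > AceView > GOP
    candidates = filter_best(candidates, lambda g: _SOURCE_RANK[rec(g).source], False)
    # 6. first gene in alphabetic order
    return min(candidates)


def assign_all(
    targets: TargetTable, restrict_to: set[str] | None = None
) -> dict[str, str]:
    """Gene assignment for every probe set (optionally a subset)."""
    groups = transcript_group_counts(targets)
    probe_sets = targets.by_probe_set.keys()
    if restrict_to is not None:
        probe_sets = [p for p in probe_sets if p in restrict_to]
    return {ps: assign_gene(ps, targets, groups) for ps in probe_sets}
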