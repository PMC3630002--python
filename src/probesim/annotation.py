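"""Probe localisation: GOP clustering and shared-transcript/exon scores.

Probes falling outside known genes are clustered into GOPs (groups of
probes): runs of probes on the same chromosome and strand whose neighbour
gaps are at most 2 kb.  For alternative probe-set pairs, localisation scores
quantify how much of the pair's transcript and exon targeting is shared;
across similarity classes these scores should increase with similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .biclustering import TargetTable

logger = logging.getLogger(__name__)


@dataclass
class GOP:
    """Group of probes: same chromosome/strand, neighbour gaps <= ``gap``."""

    id: str
    chromosome: str
    strand: str
    positions: list[int]  # sorted, 0-based


@dataclass
class LocalisationScores:
    pct_transcripts_both: float | None
    pct_transcripts_one: float | None
    pct_exon_probes_both: float | None
    pct_exon_probes_one: float | None
    pct_probes_last_exon: float
    n_exons_both: int


def cluster_gops(
    probes: Iterable[tuple[str, str, int]], gap: int = 2000
) -> list[GOP]:
    """Cluster (chromosome, strand, position) probes into GOPs.

    Positions are sorted internally, so input order is irrelevant; a new GOP
    starts wherever the distance to the previous probe exceeds ``gap``
    (a gap of exactly ``gap`` stays in the same GOP).
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, pos in probes:
        by_key.setdefault((chrom, strand), []).append(int(pos))
    gops: list[GOP] = []
    for (chrom, strand), positions in sorted(by_key.items()):
        positions.sort()
        run = [positions[0]]
        runs = []
        for pos in positions[1:]:
            if pos - run[-1] <= gap:
                run.append(pos)
            else:
                runs.append(run)
                run = [pos]
        runs.append(run)
        for k, r in enumerate(runs, start=1):
            gops.append(GOP(f"GOP_{chrom}_{strand}_{k}", chrom, strand, r))
    return gops


def pair_localisation_scores(
    ps1: str, ps2: str, targets: TargetTable, gene: str
) -> LocalisationScores:
    """Shared-localisation scores of two probe sets on their common gene.

    With T1/T2 the targeted-transcript sets and E1/E2 the targeted-exon index
    sets on ``gene``:

    - pct_transcripts_both = 100*|T1 n T2| / |T1 u T2| (None if union empty),
      pct_transcripts_one the complementary symmetric-difference share;
    - pct_exon_probes_both/one: share of the pair's exon-located probes that
      fall in shared / unshared exons.  The table records per-probe-set exon
      probe counts, not per-exon counts, so each probe set's exon probes are
      attributed uniformly over its targeted exons;
    - pct_probes_last_exon = 100 * max over the two probe sets of the
      fraction of their targeting probes located in the last exon;
    - n_exons_both = |E1 n E2|.
    """
    r1 = targets.record(ps1, gene)
    r2 = targets.record(ps2, gene)
    t1, t2 = r1.transcripts_targeted, r2.transcripts_targeted
    union = t1 | t2
    if union:
        pct_t_both = 100.0 * len(t1 & t2) / len(union)
        pct_t_one = 100.0 * len(t1 ^ t2) / len(union)
    else:
        pct_t_both = pct_t_one = None

    e1, e2 = r1.exons_targeted, r2.exons_targeted
    shared = e1 & e2

    def split_probes(rec, own: frozenset[int]):
        if rec.probes_exon == 0 or not own:
            return 0.0, 0.0
        frac_shared = len(own & shared) / len(own)
        return rec.probes_exon * frac_shared, rec.probes_exon * (1 - frac_shared)

    b1, o1 = split_probes(r1, e1)
    b2, o2 = split_probes(r2, e2)
    total_exon_probes = r1.probes_exon + r2.probes_exon
    if total_exon_probes > 0:
        pct_e_both = 100.0 * (b1 + b2) / total_exon_probes
        pct_e_one = 100.0 * (o1 + o2) / total_exon_probes
    else:
        pct_e_both = pct_e_one = None

    fracs = []
    for r in (r1, r2):
        tot = r.total_probes
        fracs.append(r.probes_last_exon / tot if tot > 0 else 0.0)
    return LocalisationScores(
        pct_transcripts_both=pct_t_both,
        pct_transcripts_one=pct_t_one,
        pct_exon_probes_both=pct_e_both,
        pct_exon_probes_one=pct_e_one,
        pct_probes_last_exon=100.0 * max(fracs),
        n_exons_both=len(shared),
    )


SCORE_FIELDS = (
    "pct_transcripts_both",
    "pct_transcripts_one",
    "pct_exon_probes_both",
    "pct_exon_probes_one",
    "pct_probes_last_exon",
    "n_exons_both",
)


def scores_by_similarity(
    pairs: Sequence,
    targets: TargetTable,
    min_probes: int = 11,
) -> pd.DataFrame:
    """Per-similarity-class summaries (mean + deciles) of localisation scores.

    ``pairs`` are PairSimilarity records.  Only pairs whose two probe sets
    each target a single gene (their common gene) with at least ``min_probes``
    probes enter the summaries — the restriction removes cross-hybridising
    probe sets whose localisation is ambiguous.
    """
    rows = []
    for p in pairs:
        a, b = p.pair
        if targets.genes_of(a) != {p.gene} or targets.genes_of(b) != {p.gene}:
            continue
        if (targets.record(a, p.gene).total_probes < min_probes
                or targets.record(b, p.gene).total_probes < min_probes):
            continue
        s = pair_localisation_scores(a, b, targets, p.gene)
        rows.append({"class": p.similarity_class,
                     **{f: getattr(s, f) for f in SCORE_FIELDS}})
    if not rows:
        logger.warning("no pair passed the localisation filters")
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    out = []
    for cls, grp in df.groupby("class"):
        row: dict = {"class": cls, "n_pairs": len(grp)}
        for f in SCORE_FIELDS:
            vals = grp[f].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                logger.warning("class %s: %s undefined for all pairs", cls, f)
                continue
            row[f"mean_{f}"] = float(vals.mean())
            for q in range(10, 100, 10):
                row[f"d{q}_{f}"] = float(np.percentile(vals, q))
        out.append(row)
    return pd.DataFrame(out).sort_values("class").reset_index(drop=True)
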