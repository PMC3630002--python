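"""Seeded synthetic datasets with planted transcript modules.

The generator emulates the inputs of the pipeline: per-network I/D/N call
matrices driven by latent transcript modules, matched raw signal matrices,
condition-group comparison designs, and a probe-target annotation table with
planted shared-transcript/exon structure.  Probe sets of the same module are
planted "same" (similar) pairs, sign-flipped modules give "anti" pairs and
distinct modules give "independent" pairs, so every downstream stage can be
scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import spawn_seeds
from .biclustering import TargetRecord, TargetTable
from .comparisons import ComparisonDesign, build_cross_design
from .covariation import VariationCallMatrix

PAIR_LABELS = ("same", "independent", "anti")


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults are desk-scale: 200 genes with 1-3 probe sets each, five
    networks built from 10x10 cross designs over fresh condition groups,
    a per-comparison change probability of 0.25 per direction, a 0.2 N
    substitution rate and a 0.02 I/D flip rate per probe set and position.
    """

    n_genes: int = 200
    probe_sets_per_gene: tuple[int, int] = (1, 3)  # inclusive uniform range
    n_networks: int = 5
    group_size: int = 10
    n_conditions: int | None = None  # default: 2 * group_size * n_networks
    p_change: float = 0.25
    epsilon: float = 0.2  # N substitution rate
    delta: float = 0.02  # I<->D flip rate
    frac_same_module: float = 0.5
    frac_anti: float = 0.1
    signal_module_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions is None:
            self.n_conditions = 2 * self.group_size * self.n_networks
        for name in ("p_change", "epsilon", "delta", "frac_same_module", "frac_anti"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_change > 0.5:
            raise ValueError("p_change must be <= 0.5 (P(I)=P(D)=p_change)")
        if self.frac_same_module + self.frac_anti > 1:
            raise ValueError("frac_same_module + frac_anti must be <= 1")
        if 2 * self.group_size * self.n_networks > self.n_conditions:
            raise ValueError(
                "infeasible group allocation: need 2*group_size*n_networks "
                f"= {2 * self.group_size * self.n_networks} conditions, "
                f"have {self.n_conditions}"
            )


@dataclass
class Dataset:
    """In-memory bundle of all pipeline inputs."""

    call_matrices: list[VariationCallMatrix]
    signals: pd.DataFrame  # conditions x probe sets, positive units
    targets: TargetTable
    designs: list[ComparisonDesign]

    def __post_init__(self) -> None:
        ids = self.call_matrices[0].probe_set_ids if self.call_matrices else []
        for m in self.call_matrices:
            if m.probe_set_ids != ids:
                raise ValueError("call matrices must share one probe-set list")
        missing = set(ids) - set(self.targets.by_probe_set)
        if missing:
            raise ValueError(f"probe sets absent from target table: {sorted(missing)[:5]}")


@dataclass
class SyntheticTruth:
    module_of: dict[str, tuple[int, int]]  # probe set -> (module id, sign)
    pair_labels: dict[tuple[str, str], str]  # alternative pair -> label
    designs: list[ComparisonDesign]

    def pairs_with_label(self, label: str) -> list[tuple[str, str]]:
        if label not in PAIR_LABELS:
            raise ValueError(f"unknown label {label!r}")
        return [p for p, l in self.pair_labels.items() if l == label]


def _draw_latent(rng: np.random.Generator, n_modules: int, m: int, p: float) -> np.ndarray:
    """Latent module calls: int8 matrix, P(I)=P(D)=p, else N."""
    u = rng.random((n_modules, m))
    out = np.zeros((n_modules, m), dtype=np.int8)
    out[u < p] = 1
    out[(u >= p) & (u < 2 * p)] = -1
    return out


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, SyntheticTruth]:
    """Generate a full synthetic dataset plus its planted truth.

    Reproducible from ``spec.seed``; each network draws from its own derived
    sub-seed so single networks regenerate independently.
    """
    master = np.random.default_rng(spec.seed)
    net_seeds = spawn_seeds(spec.seed, spec.n_networks + 2)
    layout_rng = np.random.default_rng(net_seeds[-2])
    signal_rng = np.random.default_rng(net_seeds[-1])

    # --- gene / probe-set / module layout -------------------------------
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    lo, hi = spec.probe_sets_per_gene
    ps_ids: list[str] = []
    ps_gene: dict[str, str] = {}
    gene_ps: dict[str, list[str]] = {}
    for g in genes:
        k = int(layout_rng.integers(lo, hi + 1))
        members = [f"{g}_ps{j + 1}" for j in range(k)]
        gene_ps[g] = members
        for ps in members:
            ps_ids.append(ps)
            ps_gene[ps] = g

    module_of: dict[str, tuple[int, int]] = {}
    gene_kind: dict[str, str] = {}
    next_module = 0
    for g in genes:
        members = gene_ps[g]
        if len(members) == 1:
            module_of[members[0]] = (next_module, +1)
            gene_kind[g] = "single"
            next_module += 1
            continue
        u = layout_rng.random()
        if u < spec.frac_same_module:
            gene_kind[g] = "same"
            for ps in members:
                module_of[ps] = (next_module, +1)
            next_module += 1
        elif u < spec.frac_same_module + spec.frac_anti:
            gene_kind[g] = "anti"
            module_of[members[0]] = (next_module, +1)
            for ps in members[1:]:
                module_of[ps] = (next_module, -1)
            next_module += 1
        else:
            gene_kind[g] = "independent"
            for ps in members:
                module_of[ps] = (next_module, +1)
                next_module += 1
    n_modules = next_module

    pair_labels: dict[tuple[str, str], str] = {}
    for g in genes:
        members = gene_ps[g]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                (ma, sa), (mb, sb) = module_of[a], module_of[b]
                if ma != mb:
                    label = "independent"
                elif sa == sb:
                    label = "same"
                else:
                    label = "anti"
                pair_labels[(a, b)] = label

    # --- conditions, designs, call matrices -----------------------------
    conditions = [f"cond{i + 1:04d}" for i in range(spec.n_conditions)]
    designs: list[ComparisonDesign] = []
    call_matrices: list[VariationCallMatrix] = []
    mod_idx = np.array([module_of[ps][0] for ps in ps_ids])
    sign = np.array([module_of[ps][1] for ps in ps_ids], dtype=np.int8)
    for net in range(spec.n_networks):
        rng = np.random.default_rng(net_seeds[net])
        a = conditions[2 * net * spec.group_size:(2 * net + 1) * spec.group_size]
        b = conditions[(2 * net + 1) * spec.group_size:(2 * net + 2) * spec.group_size]
        design = build_cross_design(a, b, name_a=f"net{net + 1}_A", name_b=f"net{net + 1}_B")
        designs.append(design)
        m = design.n_comparisons
        latent = _draw_latent(rng, n_modules, m, spec.p_change)
        calls = latent[mod_idx] * sign[:, None]
        # N substitution then I<->D flips, independent per probe set/position
        calls = np.where(rng.random(calls.shape) < spec.epsilon, 0, calls)
        flip = rng.random(calls.shape) < spec.delta
        calls = np.where(flip, -calls, calls).astype(np.int8)
        call_matrices.append(VariationCallMatrix(
            probe_set_ids=list(ps_ids),
            comparison_ids=[f"net{net + 1}_{cid}" for cid in design.comparison_ids()],
            codes=calls,
        ))

    # --- signals: per-condition module level + unit noise ----------------
    levels = signal_rng.normal(0.0, spec.signal_module_sd, size=(spec.n_conditions, n_modules))
    latent_sig = levels[:, mod_idx] * sign[None, :]
    latent_sig = latent_sig + signal_rng.normal(0.0, 1.0, size=latent_sig.shape)
    signals = pd.DataFrame(
        np.exp(latent_sig / 2.0) * 100.0, index=conditions, columns=ps_ids
    )

    # --- annotation with planted localisation structure ------------------
    records: list[TargetRecord] = []
    for g in genes:
        members = gene_ps[g]
        kind = gene_kind[g]
        n_tr = max(len(members) + 1, 3)
        transcripts = [f"{g}_t{t + 1}" for t in range(n_tr)]
        for j, ps in enumerate(members):
            if kind in ("same", "single"):
                # same-module probe sets share transcripts and exons
                tt = frozenset(transcripts[:2])
                exons = frozenset({1, 2, 3})
                last = 6
            elif kind == "anti" and j > 0:
                # the sign-flipped probe sets form one module: they share
                # localisation with each other but not with the first
                tt = frozenset(transcripts[1:3])
                exons = frozenset({4, 5, 6})
                last = 3
            else:
                # independent probe sets split the gene's isoforms
                tt = frozenset({transcripts[j]})
                exons = frozenset({2 * j + 1, 2 * j + 2})
                last = 3
            records.append(TargetRecord(
                probe_set=ps,
                gene=g,
                source="Ensembl",
                probes_exon=11,
                probes_intron=0,
                probes_up=0,
                probes_down=0,
                transcripts_targeted=tt,
                transcripts_untargeted=frozenset(transcripts) - tt,
                exons_targeted=exons,
                probes_last_exon=last,
            ))
    targets = TargetTable(records)

    dataset = Dataset(call_matrices, signals, targets, designs)
    truth = SyntheticTruth(module_of, pair_labels, designs)
    return dataset, truth


def truth_recovery_report(
    truth: SyntheticTruth, pair_classes: Sequence
) -> pd.DataFrame:
    """Cross-tabulate planted pair labels against computed similarity classes.

    ``pair_classes`` are PairSimilarity records (or anything with ``pair``
    and ``similarity_class``).  The returned frame carries the confusion
    counts; its ``attrs`` hold the headline recovery rates:
    same -> class >= 75 and independent -> class <= 1.
    """
    rows = []
    for p in pair_classes:
        a, b = p.pair
        key = (a, b) if (a, b) in truth.pair_labels else (b, a)
        label = truth.pair_labels.get(key)
        if label is None:
            continue
        rows.append({"label": label, "similarity_class": p.similarity_class})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no scored pair matches the planted truth")
    confusion = (
        df.groupby(["label", "similarity_class"]).size().unstack(fill_value=0)
    )
    same = df[df["label"] == "same"]
    indep = df[df["label"] == "independent"]
    confusion.attrs["recovery_same"] = (
        100.0 * (same["similarity_class"] >= 75).mean() if len(same) else float("nan")
    )
    confusion.attrs["recovery_independent"] = (
        100.0 * (indep["similarity_class"] <= 1).mean() if len(indep) else float("nan")
    )
    return confusion
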