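"""Tab-separated readers and writers for all pipeline tables.

All tables are UTF-8 TSV with a mandatory header row; list-valued cells use
";" separators.  Every reader/writer pair round-trips losslessly on valid
files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biclustering import TargetRecord, TargetTable
from .comparisons import ComparisonDesign
from .covariation import CovariationNetwork, VariationCallMatrix, encode_calls
from .similarity import PairSimilarity
from .synthetic import Dataset, SyntheticTruth

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset("IDN")


class FormatError(ValueError):
    """A table violates its format contract."""


def read_call_matrix(path) -> VariationCallMatrix:
    """Read a probe-set x comparison I/D/N call matrix.

    Header: first column holds probe-set identifiers, remaining columns are
    comparison identifiers; every cell must be I, D or N.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one comparison")
        comparison_ids = header[1:]
        probe_set_ids: list[str] = []
        strings: list[str] = []
        for row_no, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: row {row_no} has {len(fields) - 1} cells, "
                    f"expected {len(comparison_ids)}"
                )
            ps, cells = fields[0], fields[1:]
            for col_no, cell in enumerate(cells, start=1):
                if cell not in VALID_CALLS:
                    raise FormatError(
                        f"{path}: invalid call {cell!r} at row {row_no}, column {col_no}"
                    )
            if ps in probe_set_ids:
                raise FormatError(f"{path}: duplicate probe-set identifier {ps!r}")
            probe_set_ids.append(ps)
            strings.append("".join(cells))
    logger.info("read call matrix %s: %d probe sets x %d comparisons",
                path.name, len(probe_set_ids), len(comparison_ids))
    return VariationCallMatrix(probe_set_ids, comparison_ids, encode_calls(strings))


def write_call_matrix(matrix: VariationCallMatrix, path) -> None:
    path = Path(path)
    lut = np.array(["D", "N", "I"])
    with path.open("w", encoding="utf-8") as fh:
        fh.write("probe_set\t" + "\t".join(matrix.comparison_ids) + "\n")
        for ps, row in zip(matrix.probe_set_ids, matrix.codes):
            fh.write(ps + "\t" + "\t".join(lut[row + 1]) + "\n")


_TARGET_COLUMNS = [
    "probe_set", "gene", "source", "probes_exon", "probes_intron",
    "probes_up", "probes_down", "transcripts_targeted",
    "transcripts_untargeted", "exons_targeted", "probes_last_exon",
]


def _split_list(cell: str) -> frozenset[str]:
    return frozenset(x for x in str(cell).split(";") if x) if cell and not pd.isna(cell) else frozenset()


def read_target_table(path) -> TargetTable:
    """Read the probe-target annotation table (one row per probe set/gene)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        counts = {}
        for c in ("probes_exon", "probes_intron", "probes_up", "probes_down",
                  "probes_last_exon"):
            v = int(row[c])
            if v < 0:
                raise FormatError(f"{path}: negative count {c}={v} for "
                                  f"({row['probe_set']}, {row['gene']})")
            counts[c] = v
        records.append(TargetRecord(
            probe_set=row["probe_set"],
            gene=row["gene"],
            source=row["source"],
            transcripts_targeted=_split_list(row["transcripts_targeted"]),
            transcripts_untargeted=_split_list(row["transcripts_untargeted"]),
            exons_targeted=frozenset(int(x) for x in _split_list(row["exons_targeted"])),
            **counts,
        ))
    logger.info("read target table %s: %d records", path.name, len(records))
    return TargetTable(records)


def write_target_table(targets: TargetTable, path) -> None:
    targets.to_frame().to_csv(path, sep="\t", index=False)


_SIM_COLUMNS = [
    "probe_set_1", "probe_set_2", "gene", "similarity_class",
    "n_networks_similar", "n_networks", "mean_corr", "mean_anti",
    "mean_overlap",
]


def write_similarity_table(pairs: Sequence[PairSimilarity], path) -> None:
    """Write pair similarities, one row per pair, lexicographic order."""
    rows = []
    for p in sorted(pairs, key=lambda p: p.pair):
        rows.append({
            "probe_set_1": p.pair[0],
            "probe_set_2": p.pair[1],
            "gene": p.gene,
            "similarity_class": p.similarity_class,
            "n_networks_similar": p.n_similar,
            "n_networks": len(p.per_network),
            "mean_corr": p.mean_corr,
            "mean_anti": p.mean_anti,
            "mean_overlap": p.mean_overlap,
            "per_network": ";".join("1" if x else "0" for x in p.per_network),
        })
    pd.DataFrame(rows, columns=_SIM_COLUMNS + ["per_network"]).to_csv(
        path, sep="\t", index=False
    )


def read_similarity_table(path) -> list[PairSimilarity]:
    df = pd.read_csv(path, sep="\t", dtype={"per_network": str})
    out = []
    for _, row in df.iterrows():
        per_network = [c == "1" for c in str(row["per_network"]).split(";")] \
            if row.get("per_network") and not pd.isna(row["per_network"]) else []
        out.append(PairSimilarity(
            pair=(row["probe_set_1"], row["probe_set_2"]),
            gene=row["gene"],
            per_network=per_network,
            n_similar=int(row["n_networks_similar"]),
            similarity_class=int(row["similarity_class"]),
            mean_corr=float(row["mean_corr"]),
            mean_anti=float(row["mean_anti"]),
            mean_overlap=float(row["mean_overlap"]),
        ))
    return out


def write_network(network: CovariationNetwork, path) -> None:
    """Edge list TSV: ps_a, ps_b, corr, anti (absent values written 0)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("ps_a\tps_b\tcorr\tanti\n")
        for a, b, c, x in network.edges():
            fh.write(f"{a}\t{b}\t{c:.6g}\t{x:.6g}\n")


def read_design(path) -> dict[str, list[str]]:
    """Read condition groups: TSV with group_name, condition_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["group_name", "condition_id"]:
        raise FormatError(f"{path}: expected columns group_name, condition_id")
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["group_name"], []).append(row["condition_id"])
    return groups


def write_design(design: ComparisonDesign, path) -> None:
    rows = [
        {"group_name": name, "condition_id": cond}
        for name, conds in design.groups.items()
        for cond in conds
    ]
    pd.DataFrame(rows, columns=["group_name", "condition_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_probe_bed(path) -> list[tuple[str, str, int]]:
    """Read probe genomic positions from BED (0-based half-open).

    Returns (chromosome, strand, start) triples; strand defaults to '+' when
    the file has fewer than six columns.
    """
    probes = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line with fewer than 3 fields")
            strand = fields[5] if len(fields) >= 6 else "+"
            probes.append((fields[0], strand, int(fields[1])))
    return probes


# --- dataset directory layout -------------------------------------------

def write_dataset(dataset: Dataset, out_dir, truth: SyntheticTruth | None = None) -> None:
    """Write a dataset to a directory (calls_netN.tsv, design_netN.tsv,
    targets.tsv, signals.tsv and optionally truth.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (calls, design) in enumerate(zip(dataset.call_matrices, dataset.designs), 1):
        write_call_matrix(calls, out / f"calls_net{i}.tsv")
        write_design(design, out / f"design_net{i}.tsv")
    write_target_table(dataset.targets, out / "targets.tsv")
    dataset.signals.to_csv(out / "signals.tsv", sep="\t", index_label="condition")
    if truth is not None:
        rows = [
            {"probe_set_1": a, "probe_set_2": b, "label": label,
             "module_1": truth.module_of[a][0], "module_2": truth.module_of[b][0]}
            for (a, b), label in sorted(truth.pair_labels.items())
        ]
        pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    logger.info("wrote dataset to %s (%d networks, %d probe sets)",
                out, len(dataset.call_matrices),
                dataset.call_matrices[0].n_probe_sets if dataset.call_matrices else 0)


def read_dataset(in_dir) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    from .comparisons import ComparisonDesign

    src = Path(in_dir)
    call_matrices = []
    designs = []
    i = 1
    while (src / f"calls_net{i}.tsv").exists():
        call_matrices.append(read_call_matrix(src / f"calls_net{i}.tsv"))
        groups = read_design(src / f"design_net{i}.tsv")
        names = list(groups)
        if len(names) == 2:
            a, b = groups[names[0]], groups[names[1]]
            comparisons = [(x, y) for x in a for y in b]
            designs.append(ComparisonDesign(groups, comparisons, "cross_group"))
        else:
            designs.append(ComparisonDesign(groups, [], "all_pairs"))
        i += 1
    if not call_matrices:
        raise FormatError(f"{src}: no calls_net1.tsv found")
    targets = read_target_table(src / "targets.tsv")
    signals = pd.read_csv(src / "signals.tsv", sep="\t", index_col="condition")
    return Dataset(call_matrices, signals, targets, designs)
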