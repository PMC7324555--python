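"""Table readers/writers shared by the CLI and the analysis drivers.

Canonical dialect: plain TSV, one header row, UTF-8, "." decimal
separator; CSV is accepted by sniffing the delimiter.  Every reader
validates its schema and reports errors with file, row and column
context (rows are numbered from 1, excluding the header).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coverage import CopyNumberEstimate, ReplicomCoverage, mean_coverage
from .enrichment import CogAnnotation, EnrichmentResult
from .fitness import (
    BandIntensitySeries,
    CfuObservation,
    CompetitionObservation,
    FitnessEstimate,
    cfu_per_ml,
)
from .morphology import ColonySample
from .rnaseq import DECall, ExpressionMatrix

__all__ = [
    "TableError",
    "read_delimited",
    "read_competition_table",
    "read_band_table",
    "read_coverage_table",
    "read_colony_table",
    "read_expression_table",
    "read_cog_annotations",
    "read_de_list",
    "write_fitness_table",
    "write_copy_number_table",
    "write_de_table",
    "write_enrichment_table",
    "write_competition_table",
    "write_expression_table",
]


class TableError(ValueError):
    """Schema or constraint violation in an input table."""


def read_delimited(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a TSV/CSV (delimiter sniffed) and check required columns."""
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: file not found")
    with open(path, newline="", encoding="utf-8") as fh:
        head = fh.readline()
    delim = "\t" if head.count("\t") >= head.count(",") else ","
    df = pd.read_csv(path, sep=delim)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _build(path, df, builder):
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(builder(row))
        except (ValueError, TypeError) as err:
            raise TableError(f"{path}: row {i}: {err}") from err
    return out


def read_competition_table(path: str | Path) -> list[CompetitionObservation]:
    """Competition TSV: replicate_id, time_h, colonies_counted,
    dilution_factor, volume_plated_ml, n_screened, n_positive."""
    cols = [
        "replicate_id",
        "time_h",
        "colonies_counted",
        "dilution_factor",
        "volume_plated_ml",
        "n_screened",
        "n_positive",
    ]
    df = read_delimited(path, cols)

    def build(r):
        total = cfu_per_ml(
            CfuObservation(
                int(r.colonies_counted), float(r.dilution_factor), float(r.volume_plated_ml)
            )
        )
        return CompetitionObservation(
            time_h=float(r.time_h),
            cfu_total_per_ml=total,
            n_screened=int(r.n_screened),
            n_positive=float(r.n_positive),
            replicate_id=str(r.replicate_id),
        )

    return _build(path, df, build)


def read_band_table(path: str | Path) -> BandIntensitySeries:
    df = read_delimited(path, ["time_h", "insert_intensity", "reference_intensity"])
    try:
        return BandIntensitySeries(
            tuple(df.time_h.astype(float)),
            tuple(df.insert_intensity.astype(float)),
            tuple(df.reference_intensity.astype(float)),
        )
    except ValueError as err:
        raise TableError(f"{path}: {err}") from err


def read_coverage_table(path: str | Path) -> list[ReplicomCoverage]:
    """Coverage TSV with either mean-depth columns or per-replicon mapped
    bases plus lengths (from which depths are computed)."""
    df = read_delimited(path, ["strain_id"])
    depth_cols = {"coverage_chromosome", "coverage_plasmid"}
    base_cols = {
        "mapped_bases_chromosome",
        "mapped_bases_plasmid",
        "chromosome_bp",
        "plasmid_bp",
    }
    if not depth_cols <= set(df.columns) and base_cols <= set(df.columns):
        df = df.assign(
            coverage_chromosome=[
                mean_coverage(int(b), int(l))
                for b, l in zip(df.mapped_bases_chromosome, df.chromosome_bp)
            ],
            coverage_plasmid=[
                mean_coverage(int(b), int(l))
                for b, l in zip(df.mapped_bases_plasmid, df.plasmid_bp)
            ],
        )
    if not depth_cols <= set(df.columns):
        raise TableError(
            f"{path}: need coverage_chromosome/coverage_plasmid or "
            "mapped-base + length columns"
        )
    for col in ["total_reads", "reads_chromosome", "reads_plasmid"]:
        if col not in df.columns:
            df[col] = 0

    def build(r):
        total = int(r.total_reads) or int(r.reads_chromosome) + int(r.reads_plasmid)
        return ReplicomCoverage(
            strain_id=str(r.strain_id),
            total_reads=total,
            reads_chromosome=int(r.reads_chromosome),
            reads_plasmid=int(r.reads_plasmid),
            coverage_chromosome=float(r.coverage_chromosome),
            coverage_plasmid=float(r.coverage_plasmid),
        )

    return _build(path, df, build)


def read_colony_table(path: str | Path) -> list[ColonySample]:
    """Diameter TSV (strain_id, diameter_mm; one row per colony), grouped
    into one sample per strain."""
    df = read_delimited(path, ["strain_id", "diameter_mm"])
    samples = []
    for strain, grp in df.groupby("strain_id", sort=False):
        try:
            samples.append(
                ColonySample(str(strain), tuple(grp.diameter_mm.astype(float)))
            )
        except ValueError as err:
            raise TableError(f"{path}: strain {strain!r}: {err}") from err
    return samples


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Expression TSV: orf_id, length_bp, then condition.replicate columns
    (e.g. vc.1, vc.2, ox.1, ox.2)."""
    df = read_delimited(path, ["orf_id", "length_bp"])
    sample_cols = [c for c in df.columns if c not in ("orf_id", "length_bp")]
    if not sample_cols:
        raise TableError(f"{path}: no sample columns (expected condition.replicate)")
    samples = []
    for c in sample_cols:
        cond, dot, rep = c.rpartition(".")
        if not dot or not rep.isdigit():
            raise TableError(
                f"{path}: sample column {c!r} is not of the form condition.replicate"
            )
        samples.append((cond, int(rep)))
    try:
        return ExpressionMatrix(
            tuple(df.orf_id.astype(str)),
            tuple(int(x) for x in df.length_bp),
            tuple(samples),
            df[sample_cols].to_numpy(dtype=float),
        )
    except ValueError as err:
        raise TableError(f"{path}: {err}") from err


def read_cog_annotations(path: str | Path) -> list[CogAnnotation]:
    df = read_delimited(path, ["orf_id", "cog_code"])
    return _build(path, df, lambda r: CogAnnotation(str(r.orf_id), str(r.cog_code)))


def read_de_list(path: str | Path) -> set[str]:
    """One ORF id per line; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: file not found")
    out = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_fitness_table(estimates: Sequence[FitnessEstimate], path: str | Path) -> None:
    n_reps = max((len(e.per_replicate_w) for e in estimates), default=0)
    rows = []
    for e in estimates:
        row = {"time_h": e.time_h, "mean_w": e.mean_w, "sd_w": e.sd_w}
        for i in range(n_reps):
            row[f"w_rep{i + 1}"] = (
                e.per_replicate_w[i] if i < len(e.per_replicate_w) else float("nan")
            )
        row["flags"] = ";".join(e.flags)
        rows.append(row)
    _write(pd.DataFrame(rows), path)


def write_copy_number_table(
    rows: Sequence[ReplicomCoverage], estimates: Sequence[CopyNumberEstimate], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "strain_id": [r.strain_id for r in rows],
            "total_reads": [r.total_reads for r in rows],
            "reads_chromosome": [r.reads_chromosome for r in rows],
            "reads_plasmid": [r.reads_plasmid for r in rows],
            "coverage_chromosome": [r.coverage_chromosome for r in rows],
            "coverage_plasmid": [r.coverage_plasmid for r in rows],
            "copy_number": [e.copy_number_rounded for e in estimates],
        }
    )
    _write(df, path)


def write_de_table(calls: Sequence[DECall], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "orf_id": [c.orf_id for c in calls],
            "direction": [c.direction for c in calls],
            "fc_t1_c1": [c.fold_changes[0] for c in calls],
            "fc_t1_c2": [c.fold_changes[1] for c in calls],
            "fc_t2_c1": [c.fold_changes[2] for c in calls],
            "fc_t2_c2": [c.fold_changes[3] for c in calls],
        }
    )
    _write(df, path)


def write_enrichment_table(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cog_code": [r.cog_code for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
    _write(df, path)


def write_competition_table(
    observations: Sequence[CompetitionObservation],
    path: str | Path,
    dilution_factor: float = 1e5,
    volume_plated_ml: float = 0.1,
) -> None:
    """Serialize observations into the competition-table dialect.

    Total CFU/ml is decomposed into a synthetic plate count under the
    stated plating dilution, so reading the file back reproduces the
    totals (up to plate-count rounding).
    """
    rows = []
    for o in observations:
        colonies = round(o.cfu_total_per_ml * volume_plated_ml / dilution_factor)
        rows.append(
            {
                "replicate_id": o.replicate_id,
                "time_h": o.time_h,
                "colonies_counted": int(colonies),
                "dilution_factor": dilution_factor,
                "volume_plated_ml": volume_plated_ml,
                "n_screened": o.n_screened,
                "n_positive": o.n_positive,
            }
        )
    _write(pd.DataFrame(rows), path)


def write_expression_table(mat: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"orf_id": mat.orf_ids, "length_bp": mat.orf_lengths_bp})
    for j, (cond, rep) in enumerate(mat.samples):
        df[f"{cond}.{rep}"] = mat.values[:, j]
    _write(df, path)
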