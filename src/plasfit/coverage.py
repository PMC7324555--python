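"""Plasmid copy number from whole-genome sequencing coverage.

Copy number here means average plasmids per chromosome, estimated as the
ratio of mean read depth over the plasmid to mean read depth over the
chromosome.  Depth ratios are robust to the total read yield and, unlike
raw read-count ratios, do not depend on a per-library effective read
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

__all__ = [
    "ReplicomCoverage",
    "CopyNumberEstimate",
    "copy_number",
    "mean_coverage",
    "copy_number_table",
]


@dataclass(frozen=True)
class ReplicomCoverage:
    """Per-strain read accounting over the two replicons.

    ``coverage_*`` are mean depths (x).  Read counts are carried for
    bookkeeping; the estimator itself uses depths only.
    """

    strain_id: str
    total_reads: int
    reads_chromosome: int
    reads_plasmid: int
    coverage_chromosome: float
    coverage_plasmid: float

    def __post_init__(self) -> None:
        if min(self.total_reads, self.reads_chromosome, self.reads_plasmid) < 0:
            raise ValueError("read counts must be non-negative")
        if self.reads_chromosome + self.reads_plasmid > self.total_reads:
            raise ValueError("mapped reads exceed total reads")
        if self.coverage_chromosome < 0 or self.coverage_plasmid < 0:
            raise ValueError("coverages must be non-negative")


@dataclass(frozen=True)
class CopyNumberEstimate:
    strain_id: str
    copy_number_raw: float
    copy_number_rounded: float


def _round1(x: float) -> float:
    # one decimal, half away from zero (printed-table convention); repr of
    # the float keeps a clean one-decimal form
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def copy_number(cov: ReplicomCoverage) -> CopyNumberEstimate:
    """Plasmid copy number = plasmid mean depth / chromosome mean depth."""
    if cov.coverage_chromosome <= 0:
        raise ValueError(
            f"strain {cov.strain_id!r}: zero chromosome coverage, copy number undefined"
        )
    raw = cov.coverage_plasmid / cov.coverage_chromosome
    return CopyNumberEstimate(cov.strain_id, raw, _round1(raw))


def mean_coverage(mapped_bases: int, replicon_length_bp: int) -> float:
    """Mean depth over a replicon: mapped bases / replicon length."""
    if replicon_length_bp <= 0:
        raise ValueError("replicon_length_bp must be positive")
    if mapped_bases < 0:
        raise ValueError("mapped_bases must be non-negative")
    return mapped_bases / replicon_length_bp


def copy_number_table(rows: Iterable[ReplicomCoverage]) -> list[CopyNumberEstimate]:
    """One copy-number estimate per strain, input order preserved."""
    rows = list(rows)
    if not rows:
        raise ValueError("copy_number_table requires at least one row")
    out = []
    for i, row in enumerate(rows):
        try:
            out.append(copy_number(row))
        except ValueError as err:  # pragma: no cover - row identity plumbing
            raise ValueError(f"row {i} ({row.strain_id!r}): {err}") from err
    return out
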