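"""RPKM expression, replicate QC, and the replicate-consistent DE caller.

The differential-expression rule implemented here is deliberately a plain
fold-change filter, not a statistical model: with two conditions x two
replicates, an ORF is called *up* only if all four cross-condition ratios
treatment_i / control_j exceed the threshold (default 2.0), and *down*
only if all four fall below its reciprocal.  Requiring consistency across
every replicate pairing substitutes for a variance model at n=2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "DECall",
    "rpkm",
    "replicate_correlation",
    "call_de",
    "de_proportion",
]

Direction = Literal["up", "down", "none"]

#: Default RPKM floor applied before forming ratios; keeps fold-changes
#: finite when one condition is unexpressed.
DEFAULT_FLOOR = 0.1


@dataclass(frozen=True)
class ExpressionMatrix:
    """Per-ORF abundance across condition x replicate samples.

    ``samples`` is a list of (condition, replicate_index) pairs, one per
    column of ``values``.  ``units`` flags whether values are raw counts
    or RPKM.
    """

    orf_ids: tuple[str, ...]
    orf_lengths_bp: tuple[int, ...]
    samples: tuple[tuple[str, int], ...]
    values: np.ndarray  # shape (n_orfs, n_samples)
    units: Literal["counts", "rpkm"] = "rpkm"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.orf_ids), len(self.samples)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.orf_ids)} ORFs x {len(self.samples)} samples"
            )
        if len(self.orf_lengths_bp) != len(self.orf_ids):
            raise ValueError("one length per ORF required")
        if any(l <= 0 for l in self.orf_lengths_bp):
            raise ValueError("ORF lengths must be positive")
        if np.any(v < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _ in self.samples:
            seen.setdefault(cond, None)
        return list(seen)

    def columns(self, condition: str) -> np.ndarray:
        """Column indices of one condition, ordered by replicate index."""
        cols = [
            (rep, j) for j, (cond, rep) in enumerate(self.samples) if cond == condition
        ]
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return np.array([j for _, j in sorted(cols)])

    def to_rpkm(self, total_mapped_reads: Sequence[int] | None = None) -> "ExpressionMatrix":
        """Convert a counts matrix to RPKM (per-column totals default to
        the column sums)."""
        if self.units == "rpkm":
            return self
        totals = (
            np.asarray(total_mapped_reads, dtype=float)
            if total_mapped_reads is not None
            else self.values.sum(axis=0)
        )
        if np.any(totals <= 0):
            raise ValueError("total mapped reads must be positive")
        lengths = np.asarray(self.orf_lengths_bp, dtype=float)[:, None]
        vals = self.values * 1e9 / (totals[None, :] * lengths)
        return ExpressionMatrix(
            self.orf_ids, self.orf_lengths_bp, self.samples, vals, "rpkm"
        )


@dataclass(frozen=True)
class DECall:
    orf_id: str
    direction: Direction
    fold_changes: tuple[float, float, float, float]


def rpkm(reads_on_orf: int, orf_length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of ORF per million mapped reads."""
    if orf_length_bp <= 0:
        raise ValueError("orf_length_bp must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if reads_on_orf < 0:
        raise ValueError("reads_on_orf must be non-negative")
    return reads_on_orf * 1e9 / (total_mapped_reads * orf_length_bp)


def replicate_correlation(mat: ExpressionMatrix, condition: str) -> float:
    """Pearson correlation between the two replicates of one condition.

    Used as a library-quality gate (duplicates are expected to correlate
    above ~0.97 for clean preps).
    """
    cols = mat.columns(condition)
    if len(cols) != 2:
        raise ValueError(
            f"condition {condition!r} has {len(cols)} replicates; need exactly 2"
        )
    a, b = mat.values[:, cols[0]], mat.values[:, cols[1]]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("replicate vector is constant: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def call_de(
    mat: ExpressionMatrix,
    control: str | None = None,
    treatment: str | None = None,
    threshold: float = 2.0,
    floor: float = DEFAULT_FLOOR,
) -> list[DECall]:
    """Call DE ORFs by the all-four-comparisons fold-change rule.

    The matrix must hold exactly two conditions with two replicates each.
    Values below ``floor`` are raised to ``floor`` before ratios are
    formed.  The four ratios per ORF are treatment_i / control_j for
    i, j in {1, 2}; *up* requires all four > ``threshold``, *down* all
    four < 1/``threshold``.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if floor <= 0:
        raise ValueError("floor must be positive")
    conds = mat.conditions
    if control is None or treatment is None:
        if len(conds) != 2:
            raise ValueError(f"expected exactly 2 conditions, got {conds}")
        control, treatment = (control or conds[0]), (treatment or conds[1])
    ctrl_cols, trt_cols = mat.columns(control), mat.columns(treatment)
    if len(ctrl_cols) != 2 or len(trt_cols) != 2:
        raise ValueError("each condition must have exactly 2 replicates")

    vals = np.maximum(mat.values, floor)
    ctrl = vals[:, ctrl_cols]  # (n, 2)
    trt = vals[:, trt_cols]
    # ratios[:, i, j] = treatment rep i / control rep j
    ratios = trt[:, :, None] / ctrl[:, None, :]
    flat = ratios.reshape(len(mat.orf_ids), 4)
    up = np.all(flat > threshold, axis=1)
    down = np.all(flat < 1.0 / threshold, axis=1)

    calls = []
    for i, orf in enumerate(mat.orf_ids):
        direction: Direction = "up" if up[i] else "down" if down[i] else "none"
        calls.append(DECall(orf, direction, tuple(float(x) for x in flat[i])))
    return calls


def de_proportion(calls: Sequence[DECall], genome_orf_count: int) -> float:
    """Percentage of genome ORFs called DE, reported at one decimal."""
    if genome_orf_count <= 0:
        raise ValueError("genome_orf_count must be positive")
    n_de = sum(1 for c in calls if c.direction != "none")
    if n_de > genome_orf_count:
        raise ValueError("more DE calls than genome ORFs")
    return round(100.0 * n_de / genome_orf_count, 1)
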