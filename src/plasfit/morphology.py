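"""Colony-diameter distribution summaries.

Colony size is a cheap phenotype marker for compensated versus costly
plasmid carriers: ancestral plasmid-bearing colonies are small, evolved
ones large, with a threshold (1.5 mm by default in the drivers) cleanly
separating the two morphotypes.  Colonies exactly at the threshold count
in neither fraction (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["ColonySample", "DiameterSummary", "diameter_summary", "diameter_histogram"]


@dataclass(frozen=True)
class ColonySample:
    strain_id: str
    diameters_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters_mm):
            raise ValueError("diameters must be strictly positive")


class DiameterSummary(NamedTuple):
    n: int
    mean_mm: float
    sd_mm: float
    fraction_below: float
    fraction_above: float


def diameter_summary(sample: ColonySample, threshold_mm: float) -> DiameterSummary:
    """Mean, sample sd, and strict threshold fractions of colony diameters."""
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    d = np.asarray(sample.diameters_mm, dtype=float)
    if d.size == 0:
        raise ValueError(f"empty colony sample for strain {sample.strain_id!r}")
    sd = float(np.std(d, ddof=1)) if d.size >= 2 else 0.0
    return DiameterSummary(
        n=int(d.size),
        mean_mm=float(d.mean()),
        sd_mm=sd,
        fraction_below=float(np.mean(d < threshold_mm)),
        fraction_above=float(np.mean(d > threshold_mm)),
    )


def diameter_histogram(
    sample: ColonySample, bin_width_mm: float
) -> list[tuple[float, int]]:
    """Left-closed right-open bins anchored at 0; empty bins are omitted.

    Counts always sum to the sample size.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    if not sample.diameters_mm:
        return []
    d = np.asarray(sample.diameters_mm, dtype=float)
    idx = np.floor(d / bin_width_mm).astype(int)
    out: dict[int, int] = {}
    for i in idx:
        out[int(i)] = out.get(int(i), 0) + 1
    return [(round(i * bin_width_mm, 10), c) for i, c in sorted(out.items())]
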