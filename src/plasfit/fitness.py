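"""Relative-fitness estimation from serial-transfer competition assays.

A competition assay mixes a plasmid-bearing and a plasmid-free strain,
propagates the mixture through daily 1:100 serial transfers, and tracks both
subpopulations by dilution plating plus colony screening (hybridization or
PCR against a plasmid marker).  Fitness of the bearing strain relative to
the free strain is summarized by the W statistic,

    W = ln(N_t,bearing / N_0,bearing) / ln(N_t,free / N_0,free),

the ratio of realized natural-log fold-changes.  W = 1 is neutrality,
W < 1 a plasmid cost, W > 1 a bearing-strain advantage (e.g. after
compensatory evolution).

This module also covers the assay's side quantities: CFU/ml accounting,
plasmid persistence, conjugation frequency, and the gel band-intensity
readout used when the two competitors are distinguished by PCR product
size instead of colony screening.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "CfuObservation",
    "CompetitionObservation",
    "FitnessEstimate",
    "BandIntensitySeries",
    "EXTINCT",
    "cfu_per_ml",
    "strain_cfus",
    "relative_fitness_w",
    "fitness_trajectory",
    "persistence_fraction",
    "conjugation_frequency",
    "band_relative_ratio",
]

#: Sentinel W value for a bearing class that fell below plating resolution
#: (zero positive colonies among the screened subsample at t > 0).  Reported
#: instead of -inf because zero positives bounds, rather than measures, the
#: true frequency.
EXTINCT = float("nan")


class UndefinedFitnessError(ValueError):
    """The free-strain log fold-change is zero, so W is undefined."""


@dataclass(frozen=True)
class CfuObservation:
    """One plate count: colonies observed after diluting and plating.

    ``dilution_factor`` is the fold-dilution applied before plating
    (>= 1) and ``volume_plated_ml`` the volume spread on the plate.
    """

    colonies_counted: int
    dilution_factor: float
    volume_plated_ml: float

    def __post_init__(self) -> None:
        if self.colonies_counted < 0:
            raise ValueError("colonies_counted must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.volume_plated_ml <= 0:
            raise ValueError("volume_plated_ml must be positive")


@dataclass(frozen=True)
class CompetitionObservation:
    """One timepoint of a competition culture.

    ``cfu_total_per_ml`` is the total viable count; ``n_positive`` of
    ``n_screened`` randomly screened colonies carried the plasmid marker.
    Deterministic simulations may carry fractional ``n_positive`` (the
    expected count); real screens are integers.
    """

    time_h: float
    cfu_total_per_ml: float
    n_screened: int
    n_positive: float
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")
        if self.cfu_total_per_ml <= 0:
            raise ValueError("cfu_total_per_ml must be positive")
        if self.n_screened <= 0:
            raise ValueError("n_screened must be positive")
        if not 0 <= self.n_positive <= self.n_screened:
            raise ValueError("n_positive must lie in [0, n_screened]")


@dataclass(frozen=True)
class FitnessEstimate:
    """Cross-replicate W summary at one timepoint.

    ``sd_w`` is the sample (n-1) standard deviation; for a single
    replicate it is reported as 0.0 and ``flags`` carries ``"n=1"``.
    Replicates whose bearing class hit zero screened positives contribute
    the ``EXTINCT`` (NaN) sentinel and are excluded from mean/sd.
    """

    time_h: float
    per_replicate_w: tuple[float, ...]
    mean_w: float
    sd_w: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BandIntensitySeries:
    """Gel band intensities over time: competitor-specific insert band
    versus a shared single-copy chromosomal reference band (parI)."""

    time_h: tuple[float, ...]
    insert_intensity: tuple[float, ...]
    reference_intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.time_h) == len(self.insert_intensity) == len(self.reference_intensity)):
            raise ValueError("time, insert and reference series must have equal length")
        if len(self.time_h) == 0:
            raise ValueError("series must be non-empty")
        if any(x < 0 for x in self.insert_intensity):
            raise ValueError("insert intensities must be non-negative")
        if any(x <= 0 for x in self.reference_intensity):
            raise ValueError("reference intensities must be strictly positive")


def cfu_per_ml(obs: CfuObservation) -> float:
    """Viable count from a plate: colonies x dilution / volume plated."""
    return obs.colonies_counted * obs.dilution_factor / obs.volume_plated_ml


def strain_cfus(obs: CompetitionObservation) -> tuple[float, float]:
    """Split the total CFU/ml into (plasmid-bearing, plasmid-free).

    The screened subsample is treated as a binomial sample of the plate,
    so the bearing density is total x (n_positive / n_screened).  The two
    outputs sum exactly to the input total.
    """
    bearing = obs.cfu_total_per_ml * (obs.n_positive / obs.n_screened)
    return bearing, obs.cfu_total_per_ml - bearing


def relative_fitness_w(
    n_bearing_t: float,
    n_bearing_0: float,
    n_free_t: float,
    n_free_0: float,
) -> float:
    """W = ln(bearing fold-change) / ln(free fold-change).

    All four densities must be strictly positive.  If the free strain did
    not change (denominator log = 0) W is undefined and an
    :class:`UndefinedFitnessError` is raised.  A shrinking free class
    (negative denominator) yields a signed value; callers that care flag
    it (see :func:`fitness_trajectory`).
    """
    for name, v in (
        ("n_bearing_t", n_bearing_t),
        ("n_bearing_0", n_bearing_0),
        ("n_free_t", n_free_t),
        ("n_free_0", n_free_0),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    denom = math.log(n_free_t / n_free_0)
    if denom == 0.0:
        raise UndefinedFitnessError("free strain unchanged: ln fold-change is 0")
    return math.log(n_bearing_t / n_bearing_0) / denom


def persistence_fraction(obs: CompetitionObservation) -> float:
    """Fraction of screened colonies carrying the plasmid (pure-culture
    stability readout; 1.0 means the plasmid was retained by every
    screened colony)."""
    return obs.n_positive / obs.n_screened


def conjugation_frequency(
    transconjugant_cfu_per_ml: float, donor_cfu_per_ml: float
) -> float:
    """Transconjugants per donor after a mating period (dimensionless)."""
    if donor_cfu_per_ml <= 0:
        raise ValueError("donor_cfu_per_ml must be positive")
    if transconjugant_cfu_per_ml < 0:
        raise ValueError("transconjugant_cfu_per_ml must be non-negative")
    return transconjugant_cfu_per_ml / donor_cfu_per_ml


def band_relative_ratio(series: BandIntensitySeries) -> list[float]:
    """Relative competitor ratio from gel band intensities.

    At each timepoint the insert band is normalized by the reference
    (parI) band, then by the t=0 normalized value:
    r_t = (insert_t / reference_t) / (insert_0 / reference_0), so r_0 = 1
    by construction.
    """
    if series.insert_intensity[0] <= 0:
        raise ZeroDivisionError(
            "initial insert intensity is zero: relative ratio undefined"
        )
    r0 = series.insert_intensity[0] / series.reference_intensity[0]
    return [
        (ins / ref) / r0
        for ins, ref in zip(series.insert_intensity, series.reference_intensity)
    ]


def _replicate_w_series(
    obs_sorted: list[CompetitionObservation], baseline: str
) -> dict[float, float]:
    """Per-timepoint W for one replicate.  NaN marks bearing extinction."""
    t0 = obs_sorted[0]
    if t0.time_h != 0:
        raise ValueError(
            f"replicate {t0.replicate_id!r} has no time-0 baseline observation"
        )
    b_prev, f_prev = strain_cfus(t0)
    out: dict[float, float] = {}
    for obs in obs_sorted[1:]:
        b_t, f_t = strain_cfus(obs)
        if b_t == 0.0:
            out[obs.time_h] = EXTINCT
        else:
            out[obs.time_h] = relative_fitness_w(b_t, b_prev, f_t, f_prev)
        if baseline == "previous":
            b_prev, f_prev = b_t, f_t
    return out


def fitness_trajectory(
    observations: Sequence[CompetitionObservation],
    baseline: str = "cumulative",
) -> list[FitnessEstimate]:
    """W trajectory with cross-replicate mean and sample sd per timepoint.

    Observations are grouped by ``replicate_id``; every replicate needs a
    t=0 observation.  ``baseline="cumulative"`` (default) computes W at
    each time against the replicate's t=0 counts; ``baseline="previous"``
    computes it against the preceding observation (per-transfer W).

    Returned estimates cover every t > 0 present in any replicate.
    Flags: ``"n=1"`` (single informative replicate, sd reported as 0),
    ``"extinct"`` (>=1 replicate lost its bearing class below plating
    resolution), ``"free-declined"`` (free class shrank, so the W sign
    convention inverts).
    """
    if baseline not in ("cumulative", "previous"):
        raise ValueError("baseline must be 'cumulative' or 'previous'")
    by_rep: dict[str, list[CompetitionObservation]] = {}
    for obs in observations:
        by_rep.setdefault(obs.replicate_id, []).append(obs)
    per_rep = {
        rep: _replicate_w_series(sorted(group, key=lambda o: o.time_h), baseline)
        for rep, group in by_rep.items()
    }
    rep_order = list(per_rep)
    times = sorted({t for series in per_rep.values() for t in series})

    estimates: list[FitnessEstimate] = []
    for t in times:
        ws = tuple(per_rep[rep][t] for rep in rep_order if t in per_rep[rep])
        finite = [w for w in ws if math.isfinite(w)]
        flags: list[str] = []
        if len(finite) < len(ws):
            flags.append("extinct")
        # replicate free-class decline is visible as W computed from a
        # negative-log denominator; detect from the raw counts instead
        for rep in rep_order:
            group = sorted(by_rep[rep], key=lambda o: o.time_h)
            series = {o.time_h: o for o in group}
            if t in series:
                ref = group[0] if baseline == "cumulative" else _previous(group, t)
                if strain_cfus(series[t])[1] < strain_cfus(ref)[1]:
                    flags.append("free-declined")
                    break
        if not finite:
            estimates.append(
                FitnessEstimate(t, ws, EXTINCT, 0.0, tuple(dict.fromkeys(flags)))
            )
            continue
        mean_w = statistics.fmean(finite)
        if len(finite) == 1:
            warnings.warn(
                f"single replicate at t={t} h: sd_w reported as 0", stacklevel=2
            )
            flags.append("n=1")
            sd_w = 0.0
        else:
            sd_w = statistics.stdev(finite)
        estimates.append(
            FitnessEstimate(t, ws, mean_w, sd_w, tuple(dict.fromkeys(flags)))
        )
    return estimates


def _previous(
    group: list[CompetitionObservation], t: float
) -> CompetitionObservation:
    prev = group[0]
    for obs in group:
        if obs.time_h >= t:
            break
        prev = obs
    return prev
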