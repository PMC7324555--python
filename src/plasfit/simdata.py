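"""Synthetic-data generators for every input stream of the pipeline.

The centerpiece is a three-genotype serial-transfer batch model of a
plasmid competition experiment: plasmid-bearing ancestral cells (paying a
fitness cost), plasmid-bearing compensated cells (cost ameliorated by a
chromosomal mutation), and plasmid-free cells share a single limiting
resource.  Within each batch cycle the densities follow logistic growth
with a shared carrying capacity,

    dN_i/dt = m_i N_i (1 - sum(N)/K)  (+ conjugation, loss, compensation),

and at each transfer every density is divided by the dilution factor.
Observation noise enters only through the colony screen: ``n_screened``
colonies are classified binomially by genotype class, mirroring
hybridization/PCR screening of a plated subsample.

The remaining generators emulate read allocation across replicons at a
chosen plasmid copy number, lognormal expression with planted
fold-changes, Gaussian colony-diameter mixtures, and decaying gel
band-intensity series.  All generators are reproducible: same seed and
parameters, same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import truncnorm

from .coverage import ReplicomCoverage
from .fitness import BandIntensitySeries, CompetitionObservation
from .morphology import ColonySample
from .rnaseq import ExpressionMatrix

__all__ = [
    "GrowthModelParams",
    "SimulatedTrajectory",
    "ExpressionTruth",
    "compensation_sweep_params",
    "simulate_competition",
    "simulate_wgs_reads",
    "simulate_expression",
    "simulate_colonies",
    "simulate_band_series",
    "KT2440_CHROMOSOME_BP",
    "RP4_PLASMID_BP",
]

#: Published replicon lengths of the P. putida KT2440 chromosome and the
#: IncP-1 plasmid RP4, the default geometry for read-allocation simulation.
KT2440_CHROMOSOME_BP = 6_181_873
RP4_PLASMID_BP = 60_099

GENOTYPES = ("bearing_ancestral", "bearing_compensated", "free")


@dataclass(frozen=True)
class GrowthModelParams:
    """Generative parameters of the serial-transfer batch competition.

    Defaults model a succinate minimal-medium batch culture: free-strain
    Malthusian rate 0.7 / h, a 10% plasmid cost (0.63 / h), compensated
    carriers 5% above the free strain (0.735 / h), carrying capacity
    1e9 cells/ml, 24-h cycles with 1:100 transfers, equal initial mixing,
    and conjugation/loss/compensation off.
    """

    malthusian_per_h: Mapping[str, float] = field(
        default_factory=lambda: {
            "bearing_ancestral": 0.63,
            "bearing_compensated": 0.735,
            "free": 0.7,
        }
    )
    carrying_capacity_per_ml: float = 1e9
    transfer_period_h: float = 24.0
    dilution_factor: float = 100.0
    initial_density_per_ml: float = 1e7
    initial_fraction_bearing: float = 0.5
    conjugation_rate_ml_per_cell_h: float = 0.0
    segregational_loss_per_division: float = 0.0
    compensation_rate_per_cell_h: float = 0.0
    n_cycles: int = 6
    n_screened: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(GENOTYPES) - set(self.malthusian_per_h)
        if missing:
            raise ValueError(f"malthusian_per_h missing genotypes: {sorted(missing)}")
        if any(m <= 0 for m in self.malthusian_per_h.values()):
            raise ValueError("Malthusian rates must be positive")
        if self.carrying_capacity_per_ml <= 0:
            raise ValueError("carrying capacity must be positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.transfer_period_h <= 0 or self.initial_density_per_ml <= 0:
            raise ValueError("period and initial density must be positive")
        if not 0 <= self.initial_fraction_bearing <= 1:
            raise ValueError("initial_fraction_bearing must lie in [0, 1]")
        if (
            self.conjugation_rate_ml_per_cell_h < 0
            or self.compensation_rate_per_cell_h < 0
        ):
            raise ValueError("rates must be non-negative")
        if not 0 <= self.segregational_loss_per_division <= 1:
            raise ValueError("segregational loss must lie in [0, 1]")
        if self.n_cycles < 1 or self.n_screened < 1:
            raise ValueError("n_cycles and n_screened must be positive")


def compensation_sweep_params(seed: int = 0, n_cycles: int = 12) -> "GrowthModelParams":
    """Scenario parameters for a compensatory-mutation sweep.

    A 10% plasmid cost with compensated carriers 5% above the free
    strain and an ancestral-to-compensated conversion rate of 0.01 per
    cell per hour (an aggregate of mutation plus early within-cycle
    selection, chosen so the sweep completes on the few-week horizon the
    assay design probes).  The bearing fraction falls while ancestral
    carriers dominate, then recovers above its initial value as the
    compensated genotype sweeps; terminal cumulative fitness exceeds 1.
    """
    return GrowthModelParams(
        compensation_rate_per_cell_h=1e-2,
        n_cycles=n_cycles,
        seed=seed,
    )


@dataclass(frozen=True)
class SimulatedTrajectory:
    """Densities at transfer times plus the derived colony-screen record.

    ``densities`` has one row per timepoint (t=0 and after each cycle,
    sampled *before* the dilution of that transfer) and one column per
    genotype in :data:`GENOTYPES`.  ``observations`` mirror what the
    experimenter records: total CFU/ml multiplied back by the exact
    dilutions applied so far (standard serial-transfer bookkeeping that
    makes cumulative log fold-changes additive across cycles and leaves
    within-culture proportions untouched), plus the colony screen.  In
    deterministic mode ``n_positive`` is the exact expectation
    (fractional), otherwise a binomial draw.
    """

    times_h: np.ndarray
    densities: np.ndarray  # (n_times, 3)
    observations: list[CompetitionObservation]
    params: GrowthModelParams

    def bearing_fraction(self) -> np.ndarray:
        total = self.densities.sum(axis=1)
        return self.densities[:, :2].sum(axis=1) / total


def _cycle_closed_form(n: np.ndarray, m: np.ndarray, t: float) -> np.ndarray:
    return n * np.exp(m * t)


def _cycle_ode(
    n0: np.ndarray, p: GrowthModelParams, m: np.ndarray
) -> np.ndarray:
    k = p.carrying_capacity_per_ml
    gamma = p.conjugation_rate_ml_per_cell_h
    rho = p.segregational_loss_per_division
    mu = p.compensation_rate_per_cell_h

    def rhs(_t, n):
        nb, nc, nf = n
        g = 1.0 - n.sum() / k if math.isfinite(k) else 1.0
        conj = gamma * (nb + nc) * nf
        births_b = m[0] * nb * g
        births_c = m[1] * nc * g
        return [
            births_b * (1 - rho) - mu * nb + conj,
            births_c * (1 - rho) + mu * nb,
            m[2] * nf * g + rho * (births_b + births_c) - conj,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, p.transfer_period_h),
        n0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-6 * max(n0.sum(), 1.0),
    )
    if not sol.success:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"growth integration failed: {sol.message}")
    return np.maximum(sol.y[:, -1], 0.0)


def simulate_competition(
    params: GrowthModelParams, deterministic: bool = False
) -> SimulatedTrajectory:
    """Run the serial-transfer competition and emit screen observations.

    The pure exponential regime (infinite capacity, no conjugation, loss
    or compensation) is advanced by the exact closed form, so downstream
    fitness estimates recover the Malthusian-rate ratio to machine
    precision; all other regimes integrate the logistic system
    numerically.  ``deterministic=True`` suppresses the binomial colony
    screen (and is implied for the densities either way — demographic
    stochasticity is not modeled).
    """
    p = params
    m = np.array([p.malthusian_per_h[g] for g in GENOTYPES])
    rng = np.random.default_rng(p.seed)
    pure_exponential = (
        not math.isfinite(p.carrying_capacity_per_ml)
        and p.conjugation_rate_ml_per_cell_h == 0
        and p.segregational_loss_per_division == 0
        and p.compensation_rate_per_cell_h == 0
    )

    bearing0 = p.initial_density_per_ml * p.initial_fraction_bearing
    n = np.array([bearing0, 0.0, p.initial_density_per_ml - bearing0])
    times = [0.0]
    dens = [n.copy()]
    for cycle in range(1, p.n_cycles + 1):
        if pure_exponential:
            n = _cycle_closed_form(n, m, p.transfer_period_h)
        else:
            n = _cycle_ode(n, p, m)
        times.append(cycle * p.transfer_period_h)
        dens.append(n.copy())
        n = n / p.dilution_factor  # exact division at transfer

    densities = np.array(dens)
    observations = []
    for i, (t, row) in enumerate(zip(times, densities)):
        total = row.sum()
        frac = row[:2].sum() / total
        # i dilutions have been applied before this pre-transfer sample
        effective_total = total * p.dilution_factor ** max(i - 1, 0) if i else total
        if deterministic:
            n_pos = frac * p.n_screened
        else:
            n_pos = int(rng.binomial(p.n_screened, frac))
        observations.append(
            CompetitionObservation(
                time_h=t,
                cfu_total_per_ml=effective_total,
                n_screened=p.n_screened,
                n_positive=n_pos,
                replicate_id="sim",
            )
        )
    return SimulatedTrajectory(np.array(times), densities, observations, p)


def simulate_wgs_reads(
    true_copy_number: float,
    chromosome_bp: int = KT2440_CHROMOSOME_BP,
    plasmid_bp: int = RP4_PLASMID_BP,
    n_reads: int = 100_000,
    effective_read_bp: int = 150,
    seed: int | np.random.Generator = 0,
    strain_id: str = "sim",
) -> ReplicomCoverage:
    """Allocate reads between chromosome and plasmid at a given copy number.

    Each read lands on the plasmid with probability proportional to
    plasmid length x copy number (the chromosome counts once), a binomial
    model of uniform whole-genome sequencing.  Coverages are
    reads x effective read length / replicon length.  Allocated reads sum
    to ``n_reads`` exactly.
    """
    if true_copy_number <= 0:
        raise ValueError("true_copy_number must be positive")
    if min(chromosome_bp, plasmid_bp, effective_read_bp) <= 0:
        raise ValueError("lengths must be positive")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p_plasmid = (true_copy_number * plasmid_bp) / (
        chromosome_bp + true_copy_number * plasmid_bp
    )
    reads_plasmid = int(rng.binomial(n_reads, p_plasmid)) if n_reads else 0
    reads_chromosome = n_reads - reads_plasmid
    return ReplicomCoverage(
        strain_id=strain_id,
        total_reads=n_reads,
        reads_chromosome=reads_chromosome,
        reads_plasmid=reads_plasmid,
        coverage_chromosome=reads_chromosome * effective_read_bp / chromosome_bp,
        coverage_plasmid=reads_plasmid * effective_read_bp / plasmid_bp,
    )


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted ground truth accompanying a simulated expression matrix."""

    matrix: ExpressionMatrix
    planted_up: frozenset[str]
    planted_down: frozenset[str]


def simulate_expression(
    n_orfs: int = 2000,
    n_planted_up: int = 25,
    n_planted_down: int = 25,
    fold: float = 4.0,
    log_noise_sd: float = 0.2,
    seed: int = 0,
    conditions: tuple[str, str] = ("vc", "ox"),
    baseline_meanlog: float = 3.5,
    baseline_sdlog: float = 1.2,
) -> ExpressionTruth:
    """Two-condition, two-replicate lognormal expression with planted DE.

    Baseline per-ORF means are lognormal; planted ORFs have their
    treatment-condition mean multiplied (up) or divided (down) by
    ``fold``.  Each replicate value is mean x exp(N(0, log_noise_sd)).
    """
    if n_planted_up + n_planted_down > n_orfs:
        raise ValueError("planted ORFs exceed n_orfs")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if log_noise_sd < 0:
        raise ValueError("log_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    orf_ids = tuple(f"ORF_{i:04d}" for i in range(n_orfs))
    lengths = tuple(int(x) for x in rng.integers(300, 3001, size=n_orfs))
    base = np.exp(rng.normal(baseline_meanlog, baseline_sdlog, size=n_orfs))
    idx = rng.permutation(n_orfs)
    up_idx, down_idx = idx[:n_planted_up], idx[n_planted_up : n_planted_up + n_planted_down]

    ctrl_mean = base
    trt_mean = base.copy()
    trt_mean[up_idx] *= fold
    trt_mean[down_idx] /= fold

    samples = tuple(
        (cond, rep) for cond in conditions for rep in (1, 2)
    )  # control first, then treatment
    cols = []
    for cond, _rep in samples:
        mean = ctrl_mean if cond == conditions[0] else trt_mean
        noise = np.exp(rng.normal(0.0, log_noise_sd, size=n_orfs)) if log_noise_sd else 1.0
        cols.append(mean * noise)
    mat = ExpressionMatrix(orf_ids, lengths, samples, np.column_stack(cols), "rpkm")
    return ExpressionTruth(
        matrix=mat,
        planted_up=frozenset(orf_ids[i] for i in up_idx),
        planted_down=frozenset(orf_ids[i] for i in down_idx),
    )


def simulate_colonies(
    n: int, mean_mm: float, sd_mm: float, seed: int = 0, strain_id: str = "sim"
) -> ColonySample:
    """Truncated-at-zero normal colony diameters (mm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_mm <= 0 or sd_mm < 0:
        raise ValueError("mean must be positive and sd non-negative")
    rng = np.random.default_rng(seed)
    if sd_mm == 0:
        d = np.full(n, mean_mm)
    else:
        a = (0.0 - mean_mm) / sd_mm  # truncate below at zero
        d = truncnorm.rvs(a, np.inf, loc=mean_mm, scale=sd_mm, size=n, random_state=rng)
    return ColonySample(strain_id, tuple(float(x) for x in d))


def simulate_band_series(
    true_relative_ratios: Sequence[float],
    reference_level: float = 1000.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    initial_insert_fraction: float = 0.5,
) -> BandIntensitySeries:
    """Gel band intensities realizing a given relative-ratio series.

    The t=0 insert/reference intensity ratio is ``initial_insert_fraction``
    and later points scale it by the requested relative ratios, so a
    noiseless series round-trips exactly through the relative-ratio
    estimator.  ``noise_cv`` applies independent median-1 lognormal noise
    to every band (small-cv approximation of densitometry error).
    """
    ratios = np.asarray(true_relative_ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("ratios must be non-empty")
    if ratios[0] != 1.0:
        raise ValueError("first relative ratio must be 1 by definition")
    if np.any(ratios <= 0) or np.any(ratios > 1):
        raise ValueError("relative ratios must lie in (0, 1]")
    if reference_level <= 0 or noise_cv < 0:
        raise ValueError("reference_level must be positive, noise_cv non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(ratios.size) * 24.0
    ref = np.full(ratios.size, reference_level)
    ins = initial_insert_fraction * reference_level * ratios
    if noise_cv > 0:
        ins = ins * np.exp(rng.normal(0.0, noise_cv, size=ratios.size))
        ref = ref * np.exp(rng.normal(0.0, noise_cv, size=ratios.size))
    return BandIntensitySeries(
        tuple(float(x) for x in t),
        tuple(float(x) for x in ins),
        tuple(float(x) for x in ref),
    )
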