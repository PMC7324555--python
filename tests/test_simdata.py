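import math

import numpy as np
import pytest

from plasfit.coverage import copy_number
from plasfit.fitness import band_relative_ratio, fitness_trajectory
from plasfit.rnaseq import call_de
from plasfit.simdata import (
    GrowthModelParams,
    compensation_sweep_params,
    simulate_band_series,
    simulate_colonies,
    simulate_competition,
    simulate_expression,
    simulate_wgs_reads,
)


def equal_rate_params(**kw):
    rates = {"bearing_ancestral": 0.7, "bearing_compensated": 0.7, "free": 0.7}
    return GrowthModelParams(malthusian_per_h=rates, **kw)


class TestCompetition:
    def test_equal_rates_keep_bearing_fraction_constant(self):
        traj = simulate_competition(equal_rate_params(n_cycles=4), deterministic=True)
        assert traj.bearing_fraction() == pytest.approx([0.5] * 5, abs=1e-9)
        est = fitness_trajectory(traj.observations)
        assert [e.mean_w for e in est] == pytest.approx([1.0] * 4, abs=1e-9)

    def test_nonsaturating_deterministic_recovers_rate_ratio(self):
        # pure exponential growth: W equals the Malthusian-rate ratio
        p = GrowthModelParams(carrying_capacity_per_ml=float("inf"), n_cycles=5)
        traj = simulate_competition(p, deterministic=True)
        est = fitness_trajectory(traj.observations)
        for e in est:
            assert e.mean_w == pytest.approx(0.63 / 0.7, abs=1e-9)

    def test_costly_plasmid_without_compensation_declines_monotonically(self):
        p = GrowthModelParams(n_cycles=6)  # logistic, 10% cost, no rescue
        traj = simulate_competition(p, deterministic=True)
        frac = traj.bearing_fraction()
        assert np.all(np.diff(frac) < 0)

    def test_compensation_sweep_is_u_shaped_with_terminal_advantage(self):
        traj = simulate_competition(compensation_sweep_params(), deterministic=True)
        frac = traj.bearing_fraction()
        imin = int(np.argmin(frac))
        assert 0 < imin < len(frac) - 1  # falls, then rises
        assert frac[-1] > frac[0]  # recovers above the initial mix
        est = fitness_trajectory(traj.observations)
        assert est[-1].mean_w > 1.0

    def test_reproducible_given_seed(self):
        p = GrowthModelParams(n_cycles=3, seed=42)
        a = simulate_competition(p)
        b = simulate_competition(p)
        assert [o.n_positive for o in a.observations] == [
            o.n_positive for o in b.observations
        ]
        assert np.array_equal(a.densities, b.densities)

    def test_sampled_screen_counts_are_integers_within_range(self):
        traj = simulate_competition(GrowthModelParams(n_cycles=3, seed=1))
        for obs in traj.observations:
            assert float(obs.n_positive).is_integer()
            assert 0 <= obs.n_positive <= obs.n_screened

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GrowthModelParams(dilution_factor=1.0)
        with pytest.raises(ValueError):
            GrowthModelParams(initial_fraction_bearing=1.5)
        with pytest.raises(ValueError):
            GrowthModelParams(segregational_loss_per_division=-0.1)

    def test_segregational_loss_erodes_bearing_fraction_faster(self):
        base = simulate_competition(equal_rate_params(n_cycles=3), deterministic=True)
        lossy = simulate_competition(
            equal_rate_params(n_cycles=3, segregational_loss_per_division=0.02),
            deterministic=True,
        )
        assert lossy.bearing_fraction()[-1] < base.bearing_fraction()[-1]

    def test_conjugation_replenishes_bearing_class(self):
        base = simulate_competition(GrowthModelParams(n_cycles=3), deterministic=True)
        conj = simulate_competition(
            GrowthModelParams(n_cycles=3, conjugation_rate_ml_per_cell_h=1e-12),
            deterministic=True,
        )
        assert conj.bearing_fraction()[-1] > base.bearing_fraction()[-1]


class TestWgsReads:
    def test_reads_sum_exactly(self):
        cov = simulate_wgs_reads(3.0, n_reads=12345, seed=0)
        assert cov.reads_chromosome + cov.reads_plasmid == 12345

    def test_equal_lengths_copy_one_splits_evenly(self):
        counts = [
            simulate_wgs_reads(1.0, chromosome_bp=10_000, plasmid_bp=10_000,
                               n_reads=10_000, seed=s).reads_plasmid
            for s in range(20)
        ]
        assert abs(np.mean(counts) - 5000) < 100  # binomial mean n/2

    def test_copy_number_recovery_at_depth(self):
        hits = 0
        for s in range(100):
            cov = simulate_wgs_reads(3.0, n_reads=100_000, seed=s)
            if abs(copy_number(cov).copy_number_raw - 3.0) <= 0.15:
                hits += 1
        assert hits >= 95

    def test_zero_reads_degenerate(self):
        cov = simulate_wgs_reads(2.0, n_reads=0, seed=0)
        assert cov.coverage_chromosome == 0.0
        with pytest.raises(ValueError):
            copy_number(cov)


class TestExpression:
    def test_reproducible_given_seed(self):
        a = simulate_expression(n_orfs=100, seed=9)
        b = simulate_expression(n_orfs=100, seed=9)
        assert np.array_equal(a.matrix.values, b.matrix.values)
        assert a.planted_up == b.planted_up

    def test_planted_sets_disjoint_and_sized(self):
        t = simulate_expression(n_orfs=500, n_planted_up=20, n_planted_down=30, seed=2)
        assert len(t.planted_up) == 20
        assert len(t.planted_down) == 30
        assert not (t.planted_up & t.planted_down)

    def test_planted_recovery_under_noise(self):
        t = simulate_expression(
            n_orfs=2000, n_planted_up=25, n_planted_down=25,
            fold=4.0, log_noise_sd=0.2, seed=3,
        )
        calls = call_de(t.matrix, control="vc", treatment="ox")
        called = {c.orf_id for c in calls if c.direction != "none"}
        planted = t.planted_up | t.planted_down
        assert len(called & planted) >= 45  # >= 90% of 50
        assert len(called - planted) <= 5

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_expression(n_orfs=10, n_planted_up=6, n_planted_down=6)
        with pytest.raises(ValueError):
            simulate_expression(fold=1.0)


class TestColoniesAndBands:
    def test_zero_sd_is_degenerate(self):
        sample = simulate_colonies(5, 2.0, 0.0, seed=0)
        assert set(sample.diameters_mm) == {2.0}

    def test_diameters_positive_and_reproducible(self):
        a = simulate_colonies(200, 1.01, 0.17, seed=4)
        b = simulate_colonies(200, 1.01, 0.17, seed=4)
        assert a.diameters_mm == b.diameters_mm
        assert min(a.diameters_mm) > 0

    def test_band_series_noiseless_round_trip(self):
        ratios = [1.0, 0.5, 0.25]
        series = simulate_band_series(ratios, noise_cv=0.0, seed=0)
        assert band_relative_ratio(series) == pytest.approx(ratios)

    def test_band_series_noisy_recovery(self):
        ratios = [1.0, 0.5, 0.25, 0.1]
        series = simulate_band_series(ratios, noise_cv=0.05, seed=8)
        rec = band_relative_ratio(series)
        assert rec[0] == pytest.approx(1.0)
        for got, want in zip(rec[1:], ratios[1:]):
            assert abs(got - want) / want < 0.2

    def test_band_series_validation(self):
        with pytest.raises(ValueError):
            simulate_band_series([0.9, 0.5])  # must start at 1
        with pytest.raises(ValueError):
            simulate_band_series([])
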