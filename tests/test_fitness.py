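import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasfit.fitness import (
    BandIntensitySeries,
    CfuObservation,
    CompetitionObservation,
    UndefinedFitnessError,
    band_relative_ratio,
    cfu_per_ml,
    conjugation_frequency,
    fitness_trajectory,
    persistence_fraction,
    relative_fitness_w,
    strain_cfus,
)

from conftest import make_obs

positive = st.floats(min_value=1e-3, max_value=1e12, allow_nan=False)


@pytest.mark.parametrize(
    "colonies,dilution,volume,expected",
    [(150, 1e5, 0.1, 1.5e8), (0, 1e3, 0.1, 0.0), (37, 1e4, 0.05, 7.4e6)],
)
def test_cfu_per_ml_dilution_plating(colonies, dilution, volume, expected):
    assert cfu_per_ml(CfuObservation(colonies, dilution, volume)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "bad",
    [dict(colonies_counted=-1, dilution_factor=10, volume_plated_ml=0.1),
     dict(colonies_counted=5, dilution_factor=0.5, volume_plated_ml=0.1),
     dict(colonies_counted=5, dilution_factor=10, volume_plated_ml=0.0)],
)
def test_cfu_observation_rejects_invalid(bad):
    with pytest.raises(ValueError):
        CfuObservation(**bad)


@pytest.mark.parametrize(
    "total,screened,positive_n,expected",
    [
        (2e8, 200, 120, (1.2e8, 8e7)),
        (1e8, 200, 0, (0.0, 1e8)),
        (5e7, 96, 24, (1.25e7, 3.75e7)),
    ],
)
def test_strain_cfus_proportional_split(total, screened, positive_n, expected):
    obs = CompetitionObservation(0.0, total, screened, positive_n)
    bearing, free = strain_cfus(obs)
    assert bearing == pytest.approx(expected[0])
    assert free == pytest.approx(expected[1])


def test_screen_count_cannot_exceed_subsample():
    with pytest.raises(ValueError):
        CompetitionObservation(0.0, 1e8, 200, 201)


@given(total=positive, screened=st.integers(1, 500), positive_n=st.integers(0, 500))
@settings(max_examples=100, derandomize=True)
def test_strain_cfus_conserves_total(total, screened, positive_n):
    if positive_n > screened:
        positive_n = screened
    bearing, free = strain_cfus(CompetitionObservation(0.0, total, screened, positive_n))
    assert bearing + free == pytest.approx(total, rel=1e-12)
    assert bearing >= 0 and free >= 0


@pytest.mark.parametrize(
    "bt,b0,ft,f0,expected",
    [
        (1e8, 1e6, 1e8, 1e6, 1.0),
        (1e7, 1e6, 1e8, 1e6, 0.5),
        (3.2e7, 5e5, 6.4e7, 5e5, math.log(64) / math.log(128)),
    ],
)
def test_relative_fitness_w_log_ratio(bt, b0, ft, f0, expected):
    assert relative_fitness_w(bt, b0, ft, f0) == pytest.approx(expected, rel=1e-12)


@given(
    bt=positive, b0=positive, ft=positive, f0=positive,
    c=st.floats(min_value=1e-3, max_value=1e3),
)
@settings(max_examples=100, derandomize=True)
def test_relative_fitness_w_scale_invariant(bt, b0, ft, f0, c):
    if abs(math.log(ft / f0)) < 1e-6:
        ft = f0 * 2
    w = relative_fitness_w(bt, b0, ft, f0)
    assert relative_fitness_w(c * bt, c * b0, c * ft, c * f0) == pytest.approx(w, rel=1e-9)


def test_relative_fitness_w_errors():
    with pytest.raises(ValueError):
        relative_fitness_w(0, 1e6, 1e8, 1e6)
    with pytest.raises(UndefinedFitnessError):
        relative_fitness_w(1e7, 1e6, 1e6, 1e6)


def test_w_above_one_iff_bearing_outgrows_free():
    # both classes expand; bearing faster => W > 1, slower => W < 1
    assert relative_fitness_w(2e8, 1e6, 1e8, 1e6) > 1
    assert relative_fitness_w(5e7, 1e6, 1e8, 1e6) < 1


def test_trajectory_neutral_replicates_give_unit_w():
    obs = []
    for rep in "abc":
        obs.append(make_obs(0, 1e6, 1e6, replicate_id=rep))
        obs.append(make_obs(24, 1e8, 1e8, replicate_id=rep))
    (est,) = fitness_trajectory(obs)
    assert est.mean_w == pytest.approx(1.0)
    assert est.sd_w == 0.0


def test_trajectory_mean_and_sample_sd():
    # replicate Ws 0.5, 0.6, 0.7 at 24 h: free grows 100-fold, bearing 100^w
    obs = []
    for rep, w in zip("abc", (0.5, 0.6, 0.7)):
        obs.append(make_obs(0, 1e6, 1e6, replicate_id=rep))
        obs.append(make_obs(24, 1e6 * 100**w, 1e8, replicate_id=rep))
    (est,) = fitness_trajectory(obs)
    assert est.per_replicate_w == pytest.approx((0.5, 0.6, 0.7))
    assert est.mean_w == pytest.approx(0.6)
    assert est.sd_w == pytest.approx(0.1)  # n-1 denominator


def test_trajectory_single_replicate_flags_and_warns():
    obs = [make_obs(0, 1e6, 1e6), make_obs(24, 1e7, 1e8)]
    with pytest.warns(UserWarning, match="single replicate"):
        (est,) = fitness_trajectory(obs)
    assert est.sd_w == 0.0
    assert "n=1" in est.flags


def test_trajectory_missing_baseline_errors():
    with pytest.raises(ValueError, match="time-0"):
        fitness_trajectory([make_obs(24, 1e7, 1e8)])


def test_trajectory_extinct_bearing_class_is_flagged_not_infinite():
    obs = [
        make_obs(0, 1e6, 1e6),
        CompetitionObservation(24, 1e8, 200, 0, "1"),
    ]
    (est,) = fitness_trajectory(obs)
    assert math.isnan(est.mean_w)
    assert "extinct" in est.flags


def test_trajectory_per_transfer_baseline():
    # two cycles, each with free x100 and bearing x10: per-transfer W = 0.5
    obs = [
        make_obs(0, 1e6, 1e6),
        make_obs(24, 1e7, 1e8),
        make_obs(48, 1e8, 1e10),
    ]
    cum = fitness_trajectory(obs, baseline="cumulative")
    prev = fitness_trajectory(obs, baseline="previous")
    assert [e.mean_w for e in cum] == pytest.approx([0.5, 0.5])
    assert [e.mean_w for e in prev] == pytest.approx([0.5, 0.5])
    # make the second cycle neutral: cumulative and per-transfer now differ
    obs[2] = make_obs(48, 1e9, 1e10)
    assert fitness_trajectory(obs, baseline="previous")[1].mean_w == pytest.approx(1.0)
    assert fitness_trajectory(obs, baseline="cumulative")[1].mean_w == pytest.approx(
        3 / 4
    )


@pytest.mark.parametrize(
    "screened,positive_n,expected", [(200, 200, 1.0), (200, 0, 0.0), (96, 72, 0.75)]
)
def test_persistence_fraction(screened, positive_n, expected):
    obs = CompetitionObservation(24.0, 1e8, screened, positive_n)
    assert persistence_fraction(obs) == pytest.approx(expected)


@pytest.mark.parametrize(
    "trans,donor,expected", [(1.2e3, 1e7, 1.2e-4), (0, 1e7, 0.0), (5e2, 4e8, 1.25e-6)]
)
def test_conjugation_frequency(trans, donor, expected):
    assert conjugation_frequency(trans, donor) == pytest.approx(expected)


def test_conjugation_frequency_requires_donors():
    with pytest.raises(ValueError):
        conjugation_frequency(10.0, 0.0)


@pytest.mark.parametrize(
    "insert,ref,expected",
    [
        ((100, 40), (200, 160), [1.0, 0.5]),
        ((80, 80, 80), (160, 160, 160), [1.0, 1.0, 1.0]),
        ((80, 60, 20), (160, 150, 100), [1.0, 0.8, 0.4]),
    ],
)
def test_band_relative_ratio(insert, ref, expected):
    series = BandIntensitySeries(tuple(range(0, 24 * len(insert), 24)), insert, ref)
    assert band_relative_ratio(series) == pytest.approx(expected)


@given(
    insert=st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=1, max_size=8),
    ref=st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=8, max_size=8),
)
@settings(max_examples=50, derandomize=True)
def test_band_ratio_starts_at_one(insert, ref):
    n = len(insert)
    series = BandIntensitySeries(tuple(range(n)), tuple(insert), tuple(ref[:n]))
    assert band_relative_ratio(series)[0] == pytest.approx(1.0)


def test_band_ratio_zero_initial_insert_is_undefined():
    series = BandIntensitySeries((0, 24), (0, 10), (100, 100))
    with pytest.raises(ZeroDivisionError):
        band_relative_ratio(series)
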