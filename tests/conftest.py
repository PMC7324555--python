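import pytest

from plasfit.fitness import CompetitionObservation


@pytest.fixture
def table6_expected():
    """Published rounded copy numbers for the 13 sequenced strains, in
    bundled-table order (ancestral, 1-L1..3, 2-L1..3, 1-S1..3, 2-S1..3)."""
    return [3.1, 1.6, 2.0, 1.6, 1.8, 2.1, 2.4, 3.1, 3.5, 3.3, 3.7, 3.0, 3.5]


def make_obs(time_h, bearing, free, n_screened=200, replicate_id="1"):
    """Competition observation with exact class densities (fractional
    screen counts, as the deterministic simulator emits)."""
    total = bearing + free
    return CompetitionObservation(
        time_h=time_h,
        cfu_total_per_ml=total,
        n_screened=n_screened,
        n_positive=n_screened * bearing / total,
        replicate_id=replicate_id,
    )
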