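import datetime as dt

import pytest

from phenodd import DevelopmentObservation, datasets
from phenodd.synthetic_data import SyntheticConfig


@pytest.fixture
def egg_mean_obs():
    """Published egg-stage mean durations in the fitting window, one record per temperature."""
    return [
        DevelopmentObservation(f"mean-{t:g}", "egg", t, d)
        for t, d in datasets.stage_mean_durations("egg").items()
    ]


@pytest.fixture
def e2a_mean_obs():
    """Published egg-to-adult mean durations in the fitting window."""
    return [
        DevelopmentObservation(f"mean-{t:g}", "egg_to_adult", t, d)
        for t, d in datasets.stage_mean_durations("egg_to_adult").items()
    ]


@pytest.fixture
def quiet_config():
    """Noise-free, unrounded generator config for exact closed-form checks."""
    return SyntheticConfig(
        stage_lines={"egg": datasets.published_rate_line("egg")},
        duration_noise_sd=0.0,
        rounding="none",
        seed=7,
    )


@pytest.fixture
def aug_start():
    return dt.date(2021, 8, 1)
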