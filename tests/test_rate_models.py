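import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenodd import (
    DevelopmentObservation,
    datasets,
    development_rate,
    fit_stage_model,
    lower_threshold,
    ols_line,
    thermal_requirement,
)
from phenodd.synthetic_data import SyntheticConfig, gen_development


@pytest.mark.parametrize(
    "duration,rate",
    [(2.0, 0.5), (1.0, 1.0), (7.1, 1 / 7.1)],
)
def test_development_rate(duration, rate):
    obs = DevelopmentObservation("x", "egg", 20.0, duration)
    assert development_rate(obs) == pytest.approx(rate)


def test_exact_line_through_two_points():
    obs = [
        DevelopmentObservation("a", "egg", 20.0, 10.0),  # rate 0.1
        DevelopmentObservation("b", "egg", 30.0, 5.0),  # rate 0.2
    ]
    m = fit_stage_model(obs, "egg", temperatures=(20.0, 30.0))
    assert m.slope_a == pytest.approx(0.01)
    assert m.intercept_b == pytest.approx(-0.1)
    assert m.r_squared == pytest.approx(1.0)


def test_egg_group_mean_slope_matches_reported(egg_mean_obs):
    """Group-mean fit on the published egg means reproduces the reported slope 0.0289."""
    m = fit_stage_model(egg_mean_obs, "egg", fit_level="group_mean")
    assert m.slope_a == pytest.approx(0.0289, abs=0.0005)
    assert m.fit_level == "group_mean"


def test_fit_requires_two_temperatures():
    obs = [DevelopmentObservation(f"i{k}", "egg", 24.0, 4.0 + k) for k in range(5)]
    with pytest.raises(ValueError, match="2 distinct temperatures"):
        fit_stage_model(obs, "egg", temperatures=(24.0,))


def test_parameter_recovery_within_three_se():
    """120 individual rates drawn around a known line recover (a, b) within 3 SE."""
    a_true, b_true = 0.03, -0.45
    rng = np.random.default_rng(42)
    obs = []
    for t in (20.0, 24.0, 28.0, 32.0):
        rates = a_true * t + b_true + rng.normal(0, 0.01, 30)
        obs += [
            DevelopmentObservation(f"i{t}-{k}", "egg", t, 1.0 / r)
            for k, r in enumerate(rates)
        ]
    m = fit_stage_model(obs, "egg", fit_level="individual")
    x = np.array([o.temperature for o in obs])
    y = np.array([1.0 / o.duration for o in obs])
    lr = stats.linregress(x, y)
    assert abs(m.slope_a - a_true) < 3 * lr.stderr
    assert abs(m.intercept_b - b_true) < 3 * lr.intercept_stderr
    # hand-rolled OLS agrees with the library fit
    assert m.slope_a == pytest.approx(lr.slope, rel=1e-12)
    assert m.intercept_b == pytest.approx(lr.intercept, rel=1e-12)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (0.0289, -0.4536, 15.7),
        (0.0088, -0.1256, 14.3),
        (0.1, 0.0, 0.0),
    ],
)
def test_lower_threshold(a, b, expected):
    assert round(lower_threshold(a, b), 1) == expected


def test_lower_threshold_reported_pairs_reproduce_reported_column():
    """−b/a on every reported coefficient pair matches the reported threshold at 1 d.p."""
    table = datasets.published_rate_models()
    for row in table.itertuples(index=False):
        assert round(lower_threshold(row.slope_a, row.intercept_b), 1) == row.ltt


def test_zero_slope_threshold_undefined():
    with pytest.raises(ValueError, match="zero slope"):
        lower_threshold(0.0, -0.5)


def test_thermal_requirement_egg_to_adult(e2a_mean_obs):
    """Degree-day averaging of published totals reproduces the reported 285.3 DD."""
    a, b = datasets.published_rate_line("egg_to_adult")
    trd, sd = thermal_requirement(e2a_mean_obs, "egg_to_adult", lower_threshold(a, b))
    assert trd == pytest.approx(285.3, abs=0.3)


def test_thermal_requirement_single_observation():
    obs = [DevelopmentObservation("x", "pupa", 24.0, 10.0)]
    trd, sd = thermal_requirement(obs, "pupa", ltt=14.0, temperatures=(24.0,))
    assert trd == pytest.approx(100.0)
    assert sd == 0.0


def test_thermal_requirement_rejects_temperature_below_threshold():
    obs = [DevelopmentObservation("x", "egg", 14.0, 10.0)]
    with pytest.raises(ValueError, match="below the lower threshold"):
        thermal_requirement(obs, "egg", ltt=15.7, temperatures=(14.0,))


def test_noise_free_cohort_recovers_line_exactly(quiet_config):
    """Data generated exactly on a line recover a, b, R², LTT and TRD = 1/a."""
    a, b = quiet_config.stage_lines["egg"]
    obs = gen_development(quiet_config)
    for level in ("individual", "group_mean"):
        m = fit_stage_model(obs, "egg", fit_level=level)
        assert m.slope_a == pytest.approx(a, rel=1e-9)
        assert m.intercept_b == pytest.approx(b, rel=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)
        assert m.ltt == pytest.approx(-b / a, rel=1e-9)
        assert m.trd_mean == pytest.approx(1.0 / a, rel=1e-9)
        assert m.trd_sd == pytest.approx(0.0, abs=1e-6)


def test_fitted_line_vanishes_at_threshold(egg_mean_obs):
    m = fit_stage_model(egg_mean_obs, "egg", fit_level="group_mean")
    assert abs(m.slope_a * m.ltt + m.intercept_b) < 1e-12


def test_predicted_duration_decreases_above_threshold(egg_mean_obs):
    m = fit_stage_model(egg_mean_obs, "egg", fit_level="group_mean")
    temps = np.linspace(m.ltt + 0.5, 40.0, 50)
    durs = [m.predicted_duration(t) for t in temps]
    assert all(d1 > d2 for d1, d2 in zip(durs, durs[1:]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_ols_matches_brute_force_grid(seed):
    """Closed-form OLS beats/equals a grid search of SS_res on small fixtures."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 51))
    x = rng.uniform(15, 35, n)
    if np.ptp(x) < 1e-6:
        x[0] += 1.0
    y = rng.uniform(0, 1, n)
    slope, intercept, _ = ols_line(x, y)

    def ss(a, b):
        return float(np.sum((y - (a * x + b)) ** 2))

    best = ss(slope, intercept)
    # grid around the closed-form optimum: nothing nearby does better
    for da in np.linspace(-0.01, 0.01, 21):
        for db in np.linspace(-0.1, 0.1, 21):
            assert ss(slope + da, intercept + db) >= best - 1e-9

    lr = stats.linregress(x, y)
    assert slope == pytest.approx(lr.slope, rel=1e-9)
    assert intercept == pytest.approx(lr.intercept, rel=1e-9)


def test_trd_converges_to_reciprocal_slope(quiet_config):
    """With fitting and averaging windows equal and no noise, TRD = 1/slope."""
    obs = gen_development(quiet_config)
    m = fit_stage_model(obs, "egg", fit_level="group_mean")
    trd, _ = thermal_requirement(obs, "egg", m.ltt)
    assert trd == pytest.approx(1.0 / m.slope_a, rel=1e-9)


def test_composite_larvae_stage_sums_instars():
    """'larvae' fits the per-individual sum of L1..L6 durations."""
    cfg = SyntheticConfig(duration_noise_sd=0.0, rounding="none", seed=1)
    obs = gen_development(cfg)
    m = fit_stage_model(obs, "larvae", fit_level="group_mean")
    expected_dur_24 = sum(
        1.0 / (a * 24.0 + b)
        for s, (a, b) in cfg.stage_lines.items()
        if s.startswith("L")
    )
    assert m.predicted_duration(24.0) == pytest.approx(expected_dur_24, rel=0.05)
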