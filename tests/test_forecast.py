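import datetime as dt
import math

import pytest
from hypothesis import given, settings, strategies as st

from phenodd import (
    InsufficientAccumulationError,
    StageRateModel,
    TemperatureSeries,
    backcast_oviposition,
    daily_degree_days,
    datasets,
    forecast_deviation,
    forecast_emergence,
    forecast_stagewise,
    lower_threshold,
)


def _model(stage, ltt, trd):
    # minimal stage model carrier for chaining tests
    a = 1.0 / trd
    return StageRateModel(
        stage=stage, slope_a=a, intercept_b=-a * ltt, r_squared=1.0,
        ltt=ltt, trd_mean=trd, trd_sd=0.0,
        temperatures_used=(20.0, 24.0, 28.0, 32.0), fit_level="group_mean",
    )


@pytest.mark.parametrize(
    "t_min,t_max,ltt,expected",
    [
        (24.0, 24.0, 14.4, 9.6),
        (10.0, 18.8, 14.4, 0.0),   # mean exactly at threshold
        (8.0, 12.0, 14.4, 0.0),    # below threshold clamps to zero
        (18.0, 28.0, 14.4, 8.6),
    ],
)
def test_daily_degree_days(t_min, t_max, ltt, expected):
    assert daily_degree_days(t_min, t_max, ltt) == pytest.approx(expected)


def test_daily_degree_days_rejects_inverted_range():
    with pytest.raises(ValueError):
        daily_degree_days(25.0, 20.0, 14.4)


def test_constant_24_matches_observed_rearing_duration(e2a_mean_obs, aug_start):
    """Degree-day forecast at 24 °C agrees with the observed 29.5-day rearing total."""
    from phenodd import thermal_requirement

    a, b = datasets.published_rate_line("egg_to_adult")
    ltt = lower_threshold(a, b)
    trd, _ = thermal_requirement(e2a_mean_obs, "egg_to_adult", ltt)
    series = TemperatureSeries.constant(aug_start, 60, 24.0)
    fc = forecast_emergence(series, aug_start, ltt, trd)
    assert abs(fc.duration_days - 29.5) <= 0.5


def test_single_day_when_temperature_equals_ltt_plus_trd(aug_start):
    series = TemperatureSeries.constant(aug_start, 10, 34.4)
    fc = forecast_emergence(series, aug_start, ltt=14.4, trd=20.0)
    assert fc.duration_days == 1
    assert fc.predicted_date == aug_start


def test_insufficient_accumulation_carries_shortfall(aug_start):
    series = TemperatureSeries.constant(aug_start, 30, 12.0)  # always below LTT
    with pytest.raises(InsufficientAccumulationError) as exc:
        forecast_emergence(series, aug_start, ltt=14.4, trd=100.0)
    assert exc.value.shortfall == pytest.approx(100.0)


def test_cumulative_trace_non_decreasing_and_crossing(aug_start):
    series = TemperatureSeries.constant(aug_start, 60, 24.0)
    fc = forecast_emergence(series, aug_start, ltt=14.4, trd=100.0)
    assert all(a <= b for a, b in zip(fc.cumulative_dd, fc.cumulative_dd[1:]))
    assert fc.cumulative_dd[-1] >= 100.0
    assert fc.cumulative_dd[-2] < 100.0


def test_stagewise_matches_observed_28C_row(aug_start):
    """Chained per-stage forecasts at 28 °C track the observed stage durations."""
    table = datasets.published_rate_models().set_index("stage")
    durations = datasets.stage_duration_summary()
    series = TemperatureSeries.constant(aug_start, 120, 28.0)
    stages = ["egg", "L1", "L2", "L3", "L4", "L5", "L6", "pupa"]
    models = [
        _model(s, table.loc[s, "ltt"], table.loc[s, "trd_mean"]) for s in stages
    ]
    chain = forecast_stagewise(series, aug_start, models)
    obs28 = durations[durations["temperature"] == 28.0].set_index("stage")["mean_days"]
    for stage, fc in zip(stages, chain):
        assert abs(fc.duration_days - obs28[stage]) <= 1.0


def test_stagewise_single_stage_reduces_to_emergence(aug_start):
    series = TemperatureSeries.constant(aug_start, 60, 24.0)
    m = _model("egg_to_adult", 14.4, 285.3)
    [chained] = forecast_stagewise(series, aug_start, [m])
    direct = forecast_emergence(series, aug_start, 14.4, 285.3)
    assert chained == direct


def test_stagewise_total_bounded_below_by_composite(aug_start):
    """Chaining discards sub-day residuals, so it can only run longer than the
    composite forecast, and by at most one day per stage boundary."""
    table = datasets.published_rate_models().set_index("stage")
    series = TemperatureSeries.constant(aug_start, 120, 24.0)
    stages = ["egg", "L1", "L2", "L3", "L4", "L5", "L6", "pupa"]
    models = [_model(s, table.loc[s, "ltt"], table.loc[s, "trd_mean"]) for s in stages]
    chain = forecast_stagewise(series, aug_start, models)
    total = (chain[-1].predicted_date - aug_start).days + 1
    composite = forecast_emergence(
        series, aug_start, table.loc["egg_to_adult", "ltt"],
        table.loc["egg_to_adult", "trd_mean"],
    ).duration_days
    assert total >= composite - len(stages)


def test_forecast_deviation_field_validation_rows():
    """Signed deviation ranges reproduce the three field-validation rows."""
    for site, expected in {
        "Cheongju": (2, 4), "Boeun": (-1, 1), "Taean": (4, 6),
    }.items():
        rec = datasets.eclosion_validation()[site]
        dev = forecast_deviation(rec["predicted"], list(rec["observed"]))
        assert (dev.deviation_min, dev.deviation_max) == expected


def test_forecast_deviation_singleton_zero():
    d = dt.date(2021, 9, 22)
    dev = forecast_deviation(d, [d])
    assert (dev.deviation_min, dev.deviation_max) == (0, 0)


def test_backcast_inverts_forecast(aug_start):
    series = TemperatureSeries.constant(aug_start, 60, 24.0)
    fc = forecast_emergence(series, aug_start, ltt=14.4, trd=285.3)
    assert backcast_oviposition(series, fc.predicted_date, 14.4, 285.3) == aug_start


# --- properties -----------------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    temp=st.floats(min_value=16.0, max_value=36.0),
    ltt=st.floats(min_value=10.0, max_value=15.7),
    trd=st.floats(min_value=10.0, max_value=300.0),
)
def test_constant_temperature_closed_form(temp, ltt, trd):
    """Accumulation loop equals ceil(TRD/(T−LTT)) at constant temperature."""
    if temp <= ltt + 0.5:
        return
    start = dt.date(2021, 8, 1)
    n = math.ceil(trd / (temp - ltt)) + 2
    series = TemperatureSeries.constant(start, n, temp)
    fc = forecast_emergence(series, start, ltt, trd)
    assert fc.duration_days == math.ceil(trd / (temp - ltt))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(shift=st.integers(min_value=-30, max_value=30), seed=st.integers(0, 1000))
def test_translation_invariance(shift, seed):
    from phenodd.synthetic_data import SyntheticConfig, gen_weather

    cfg = SyntheticConfig(seed=seed)
    start = dt.date(2021, 8, 1)
    series = gen_weather(cfg, start, 90)
    shifted = TemperatureSeries(
        tuple(d + dt.timedelta(days=shift) for d in series.dates),
        series.t_min, series.t_max,
    )
    fc = forecast_emergence(series, start, 14.4, 150.0)
    fc2 = forecast_emergence(shifted, start + dt.timedelta(days=shift), 14.4, 150.0)
    assert fc2.predicted_date == fc.predicted_date + dt.timedelta(days=shift)


def test_monotone_in_temperature_and_trd(aug_start):
    base = TemperatureSeries.constant(aug_start, 120, 22.0)
    fc_base = forecast_emergence(base, aug_start, 14.4, 200.0)
    # warm one mid-series day: never later
    warmer_mins = list(base.t_min)
    warmer_maxs = list(base.t_max)
    warmer_mins[5] += 5.0
    warmer_maxs[5] += 5.0
    warmer = TemperatureSeries(base.dates, tuple(warmer_mins), tuple(warmer_maxs))
    assert forecast_emergence(warmer, aug_start, 14.4, 200.0).predicted_date <= fc_base.predicted_date
    # larger requirement: never earlier
    assert forecast_emergence(base, aug_start, 14.4, 250.0).predicted_date >= fc_base.predicted_date
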