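"""Degree-day accumulation and emergence forecasting over daily temperature series.

A stage completes when the running sum of daily degree-days

    DD_day = max(0, (t_min + t_max)/2 - LTT)

first reaches the stage's thermal requirement TRD. Accumulation is at whole-
day granularity with ceiling semantics (emergence on the day the sum first
reaches TRD); days whose mean temperature falls below the threshold
contribute zero, never negative. For a constant-temperature series this
reduces to predicted duration = ceil(TRD / (T - LTT)).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import TemperatureSeries
from .rate_models import StageRateModel


class InsufficientAccumulationError(ValueError):
    """The series ended before the thermal requirement was reached."""

    def __init__(self, required: float, accumulated: float):
        self.required = required
        self.accumulated = accumulated
        self.shortfall = required - accumulated
        super().__init__(
            f"insufficient thermal accumulation: series provides {accumulated:.1f} "
            f"of {required:.1f} required degree-days (shortfall {self.shortfall:.1f})"
        )


@dataclass(frozen=True)
class EmergenceForecast:
    """Predicted completion date with its cumulative degree-day trace.

    ``cumulative_dd[i]`` is the accumulation through the i-th day counted
    from ``start_date`` inclusive; ``predicted_date`` is the first date on
    which it reaches ``trd``.
    """

    start_date: _dt.date
    predicted_date: _dt.date
    cumulative_dd: tuple[float, ...]
    ltt: float
    trd: float

    @property
    def duration_days(self) -> int:
        """Days from start to predicted completion, counting the start day."""
        return (self.predicted_date - self.start_date).days + 1


@dataclass(frozen=True)
class ForecastDeviation:
    """Signed day range (earliest, latest observed − predicted); positive = late."""

    deviation_min: int
    deviation_max: int

    def __post_init__(self):
        if self.deviation_min > self.deviation_max:
            raise ValueError("deviation_min > deviation_max")


def daily_degree_days(t_min: float, t_max: float, ltt: float) -> float:
    """Degree-days contributed by one day: max(0, (t_min+t_max)/2 - ltt)."""
    if t_min > t_max:
        raise ValueError(f"t_min {t_min} > t_max {t_max}")
    return max(0.0, (t_min + t_max) / 2.0 - ltt)


def forecast_emergence(
    series: TemperatureSeries,
    start_date: _dt.date,
    ltt: float,
    trd: float,
) -> EmergenceForecast:
    """Accumulate degree-days from ``start_date`` (inclusive) until ``trd`` is reached."""
    if trd <= 0:
        raise ValueError(f"thermal requirement must be positive, got {trd}")
    start = series.index_of(start_date)
    total = 0.0
    trace: list[float] = []
    for i in range(start, len(series)):
        total += daily_degree_days(series.t_min[i], series.t_max[i], ltt)
        trace.append(total)
        if total >= trd:
            return EmergenceForecast(
                start_date=start_date,
                predicted_date=series.dates[i],
                cumulative_dd=tuple(trace),
                ltt=ltt,
                trd=trd,
            )
    raise InsufficientAccumulationError(required=trd, accumulated=total)


def forecast_stagewise(
    series: TemperatureSeries,
    start_date: _dt.date,
    models: Sequence[StageRateModel],
) -> list[EmergenceForecast]:
    """Chain per-stage forecasts; each stage starts the day after the previous completes.

    Sub-day residual heat is not carried across stage boundaries, a
    conservative bias of at most one day per stage (observations that
    calibrated the models were themselves at 24-h cadence).
    """
    if not models:
        raise ValueError("no stage models supplied")
    out: list[EmergenceForecast] = []
    cursor = start_date
    for model in models:
        fc = forecast_emergence(series, cursor, model.ltt, model.trd_mean)
        out.append(fc)
        cursor = fc.predicted_date + _dt.timedelta(days=1)
    return out


def backcast_oviposition(
    series: TemperatureSeries,
    peak_date: _dt.date,
    ltt: float,
    trd: float,
) -> _dt.date:
    """Invert the forecast: walk backwards from an adult-catch peak to the
    latest start date whose accumulation through ``peak_date`` reaches ``trd``."""
    end = series.index_of(peak_date)
    total = 0.0
    for i in range(end, -1, -1):
        total += daily_degree_days(series.t_min[i], series.t_max[i], ltt)
        if total >= trd:
            return series.dates[i]
    raise InsufficientAccumulationError(required=trd, accumulated=total)


def forecast_deviation(
    predicted: _dt.date, observed_dates: Iterable[_dt.date]
) -> ForecastDeviation:
    """Signed deviation range in days; positive when observation is later than prediction."""
    observed = list(observed_dates)
    if not observed:
        raise ValueError("observed_dates is empty")
    deltas = [(d - predicted).days for d in observed]
    return ForecastDeviation(deviation_min=min(deltas), deviation_max=max(deltas))
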