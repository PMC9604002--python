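"""CSV table ingestion and the pipeline's domain types.

Four long-format CSV schemas, all comma-separated with a mandatory header
and "." decimal point:

``development.csv``
    individual_id, stage, temperature, duration
``temperature.csv``
    date, t_min, t_max           (ISO-8601 dates; constant series: t_min == t_max)
``feeding.csv``
    instar, temperature, w_before, w_after, ctrl_before, ctrl_after
``viability.csv``
    temperature, replicate, n_exposed, n_succeeded, endpoint

All temperatures are degrees Celsius; weights are grams; durations are days.
Validation is total: every row either loads as a valid record or raises a
:class:`TableValidationError` naming the offending line.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed set of life-stage labels. ``egg_to_adult`` denotes the full
#: development period (sum of all stage durations for an individual).
STAGES = ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "pupa", "egg_to_adult")

#: Larval instar labels in molt order.
LARVAL_STAGES = ("L1", "L2", "L3", "L4", "L5", "L6")

VIABILITY_ENDPOINTS = ("hatch", "larval_survival")


class TableValidationError(ValueError):
    """A CSV row violated a schema invariant. Carries the 1-based data-row index."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"row {line}: " if line is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class DevelopmentObservation:
    """One individual's observed duration in one life stage at one rearing temperature.

    Durations are observed at 24-h cadence, so ``duration >= 1`` day.
    """

    individual_id: str
    stage: str
    temperature: float
    duration: float

    def __post_init__(self):
        if self.stage not in STAGES:
            raise TableValidationError(
                f"unknown stage {self.stage!r}; valid labels: {', '.join(STAGES)}"
            )
        if not self.duration >= 1:
            raise TableValidationError(
                f"duration must be >= 1 day (24-h observation cadence), got {self.duration}"
            )


@dataclass(frozen=True)
class FeedingObservation:
    """Paired leaf weighings for one larva with its untreated evaporation control.

    ``ctrl_before``/``ctrl_after`` are the weights of the matched untreated
    leaf (mean of the control group); controls can only lose water, so
    ``ctrl_after <= ctrl_before``.
    """

    instar: int
    temperature: float
    w_before: float
    w_after: float
    ctrl_before: float
    ctrl_after: float

    def __post_init__(self):
        if not 1 <= int(self.instar) <= 6:
            raise TableValidationError(f"instar must be 1-6, got {self.instar}")
        for name in ("w_before", "w_after", "ctrl_before", "ctrl_after"):
            if not getattr(self, name) > 0:
                raise TableValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.ctrl_after > self.ctrl_before:
            raise TableValidationError(
                "control leaf gained weight: ctrl_after "
                f"{self.ctrl_after} > ctrl_before {self.ctrl_before}"
            )


@dataclass(frozen=True)
class ViabilityRecord:
    """Replicate count of successes (hatched eggs or surviving larvae) out of exposed."""

    temperature: float
    replicate: int
    n_exposed: int
    n_succeeded: int
    endpoint: str

    def __post_init__(self):
        if self.endpoint not in VIABILITY_ENDPOINTS:
            raise TableValidationError(
                f"unknown endpoint {self.endpoint!r}; valid: {', '.join(VIABILITY_ENDPOINTS)}"
            )
        if not 0 <= self.n_succeeded <= self.n_exposed:
            raise TableValidationError(
                f"need 0 <= n_succeeded <= n_exposed, got {self.n_succeeded}/{self.n_exposed}"
            )


@dataclass(frozen=True)
class TemperatureSeries:
    """Gap-free daily min/max temperature series driving degree-day accumulation.

    Constant-temperature series are encoded with ``t_min == t_max``.
    """

    dates: tuple[_dt.date, ...]
    t_min: tuple[float, ...]
    t_max: tuple[float, ...]

    def __post_init__(self):
        n = len(self.dates)
        if n == 0:
            raise TableValidationError("temperature series is empty")
        if len(self.t_min) != n or len(self.t_max) != n:
            raise TableValidationError("dates/t_min/t_max length mismatch")
        for i, (lo, hi) in enumerate(zip(self.t_min, self.t_max)):
            if lo > hi:
                raise TableValidationError(f"t_min {lo} > t_max {hi} on {self.dates[i]}")
        for prev, cur in zip(self.dates, self.dates[1:]):
            delta = (cur - prev).days
            if delta == 0:
                raise TableValidationError(f"duplicate date {cur}")
            if delta != 1:
                raise TableValidationError(f"gap in series: {prev} is not followed by {cur}")

    def __len__(self) -> int:
        return len(self.dates)

    def index_of(self, date: _dt.date) -> int:
        off = (date - self.dates[0]).days
        if not 0 <= off < len(self.dates):
            raise KeyError(f"{date} outside series [{self.dates[0]}, {self.dates[-1]}]")
        return off

    @classmethod
    def constant(cls, start: _dt.date, n_days: int, temperature: float) -> "TemperatureSeries":
        """Constant-temperature series of ``n_days`` days (incubator conditions)."""
        dates = tuple(start + _dt.timedelta(days=i) for i in range(n_days))
        temps = (float(temperature),) * n_days
        return cls(dates, temps, temps)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        dates = tuple(
            d.date() if isinstance(d, (pd.Timestamp, _dt.datetime)) else d for d in df["date"]
        )
        return cls(dates, tuple(map(float, df["t_min"])), tuple(map(float, df["t_max"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": [d.isoformat() for d in self.dates],
             "t_min": self.t_min, "t_max": self.t_max}
        )


# ---------------------------------------------------------------------------
# readers / writers

def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{path.name}: missing required column(s) {missing}; header is {list(df.columns)}"
        )
    return df


def _build_rows(df: pd.DataFrame, factory) -> list:
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(factory(row))
        except TableValidationError as exc:
            raise TableValidationError(str(exc), line=i) from None
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"malformed row: {exc}", line=i) from None
    return out


def read_development_table(path) -> list[DevelopmentObservation]:
    """Read a long-format development table; every row validated."""
    df = _read_csv(path, ["individual_id", "stage", "temperature", "duration"])
    return _build_rows(
        df,
        lambda r: DevelopmentObservation(
            str(r.individual_id), str(r.stage), float(r.temperature), float(r.duration)
        ),
    )


def write_development_table(observations: Iterable[DevelopmentObservation], path) -> None:
    pd.DataFrame(
        [
            {"individual_id": o.individual_id, "stage": o.stage,
             "temperature": o.temperature, "duration": o.duration}
            for o in observations
        ]
    ).to_csv(path, index=False)


def read_temperature_series(path) -> TemperatureSeries:
    """Read a dated daily temperature table into a gap-free series."""
    df = _read_csv(path, ["date", "t_min", "t_max"])
    try:
        dates = [_dt.date.fromisoformat(str(d)) for d in df["date"]]
    except ValueError as exc:
        raise TableValidationError(f"bad ISO date: {exc}") from None
    return TemperatureSeries(
        tuple(dates), tuple(map(float, df["t_min"])), tuple(map(float, df["t_max"]))
    )


def write_temperature_series(series: TemperatureSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_feeding_table(path) -> list[FeedingObservation]:
    df = _read_csv(
        path, ["instar", "temperature", "w_before", "w_after", "ctrl_before", "ctrl_after"]
    )
    return _build_rows(
        df,
        lambda r: FeedingObservation(
            int(r.instar), float(r.temperature), float(r.w_before),
            float(r.w_after), float(r.ctrl_before), float(r.ctrl_after),
        ),
    )


def write_feeding_table(observations: Iterable[FeedingObservation], path) -> None:
    pd.DataFrame(
        [
            {"instar": o.instar, "temperature": o.temperature,
             "w_before": o.w_before, "w_after": o.w_after,
             "ctrl_before": o.ctrl_before, "ctrl_after": o.ctrl_after}
            for o in observations
        ]
    ).to_csv(path, index=False)


def read_viability_table(path) -> list[ViabilityRecord]:
    df = _read_csv(path, ["temperature", "replicate", "n_exposed", "n_succeeded", "endpoint"])
    return _build_rows(
        df,
        lambda r: ViabilityRecord(
            float(r.temperature), int(r.replicate), int(r.n_exposed),
            int(r.n_succeeded), str(r.endpoint),
        ),
    )


def write_viability_table(records: Iterable[ViabilityRecord], path) -> None:
    pd.DataFrame(
        [
            {"temperature": r.temperature, "replicate": r.replicate,
             "n_exposed": r.n_exposed, "n_succeeded": r.n_succeeded,
             "endpoint": r.endpoint}
            for r in records
        ]
    ).to_csv(path, index=False)


def observations_to_frame(observations: Iterable[DevelopmentObservation]) -> pd.DataFrame:
    """Long DataFrame view of development observations (one row per record)."""
    return pd.DataFrame(
        [
            {"individual_id": o.individual_id, "stage": o.stage,
             "temperature": o.temperature, "duration": o.duration}
            for o in observations
        ]
    )
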