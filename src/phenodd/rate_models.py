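"""Linear development-rate models, lower temperature thresholds, thermal constants.

The model: development rate ``y = 1/duration`` (1/day) is linear in rearing
temperature ``x`` over the species' favourable range, ``y = a*x + b``.
Two derived quantities drive all downstream forecasting:

* the lower temperature threshold (LTT), the x-intercept ``-b/a`` where the
  extrapolated rate reaches zero, and
* the thermal requirement (TRD), the degree-days a stage needs to complete.
  Under constant rearing the per-individual degree-day total is
  ``duration * (T - LTT)``; the TRD is the mean of the per-temperature group
  means of that quantity, with its across-temperature SD as dispersion.

Fits are ordinary least squares via the closed-form normal equations for a
single regressor (implemented directly, cross-checked against
``scipy.stats.linregress`` in the test suite). The default fitting window is
{20, 24, 28, 32} °C: extreme temperatures where survival collapses are
excluded because the rate response is no longer linear there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import DevelopmentObservation, LARVAL_STAGES, observations_to_frame

#: Fitting window: rearing temperatures retained for regression (°C).
DEFAULT_TEMPERATURES = (20.0, 24.0, 28.0, 32.0)

FitLevel = Literal["individual", "group_mean"]


@dataclass(frozen=True)
class StageRateModel:
    """Fitted rate line for one stage plus its derived thermal parameters.

    ``slope_a`` is the rate gain per °C (1/(day·°C)); ``intercept_b`` the rate
    at 0 °C (1/day, negative in practice); ``ltt`` is −b/a; ``trd_mean``/
    ``trd_sd`` the thermal requirement in degree-days. ``trd_sd_individual``
    is the pooled per-individual SD, reported only for individual-level data.
    """

    stage: str
    slope_a: float
    intercept_b: float
    r_squared: float
    ltt: float
    trd_mean: float
    trd_sd: float
    temperatures_used: tuple[float, ...]
    fit_level: FitLevel
    trd_sd_individual: float | None = None

    def rate_at(self, temperature: float) -> float:
        return self.slope_a * temperature + self.intercept_b

    def predicted_duration(self, temperature: float) -> float:
        """Model-implied duration 1/(a·T+b); valid only above the LTT."""
        r = self.rate_at(temperature)
        if r <= 0:
            raise ValueError(f"temperature {temperature} is at or below the LTT {self.ltt:.1f}")
        return 1.0 / r

    def summary_row(self) -> dict:
        """One row of a summary table, at conventional reporting precision."""
        return {
            "stage": self.stage,
            "slope_a": round(self.slope_a, 4),
            "intercept_b": round(self.intercept_b, 4),
            "r_squared": round(self.r_squared, 4),
            "ltt": round(self.ltt, 1),
            "trd_mean": round(self.trd_mean, 1),
            "trd_sd": round(self.trd_sd, 1),
            "fit_level": self.fit_level,
        }


def development_rate(obs: DevelopmentObservation) -> float:
    """Development rate 1/duration (1/day) for a single observation."""
    if obs.duration <= 0:
        raise ValueError(f"non-positive duration {obs.duration}")
    return 1.0 / obs.duration


def ols_line(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Closed-form simple OLS: returns (slope, intercept, r_squared).

    Normal equations for one regressor: slope = Sxy/Sxx about the means.
    R² is 1 − SS_res/SS_tot on the fitted points (defined as 1.0 when the
    response is constant and the fit is exact).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a line")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero temperature variance: all x identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def lower_threshold(slope_a: float, intercept_b: float) -> float:
    """Lower temperature threshold: the x-intercept −b/a of the rate line."""
    if slope_a == 0:
        raise ValueError("zero slope: lower threshold undefined")
    return -intercept_b / slope_a


def _stage_durations(
    observations: Iterable[DevelopmentObservation],
    stage: str,
    temperatures: Sequence[float],
) -> pd.DataFrame:
    """Rows for one stage restricted to the fitting window.

    ``larvae`` is a composite stage: the per-individual sum of L1..L6
    durations, requiring all six instars for an individual to contribute.
    """
    df = observations_to_frame(list(observations))
    if df.empty:
        raise ValueError("no observations supplied")
    temps = set(float(t) for t in temperatures)
    df = df[df["temperature"].isin(temps)]
    if stage == "larvae":
        sub = df[df["stage"].isin(LARVAL_STAGES)]
        grouped = sub.groupby(["individual_id", "temperature"]).agg(
            duration=("duration", "sum"), n_stages=("stage", "nunique")
        )
        grouped = grouped[grouped["n_stages"] == len(LARVAL_STAGES)].reset_index()
        out = grouped[["individual_id", "temperature", "duration"]]
    else:
        out = df[df["stage"] == stage][["individual_id", "temperature", "duration"]]
    if out.empty:
        raise ValueError(f"no observations for stage {stage!r} in window {sorted(temps)}")
    return out.reset_index(drop=True)


def fit_stage_model(
    observations: Iterable[DevelopmentObservation],
    stage: str,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    fit_level: FitLevel = "individual",
) -> StageRateModel:
    """Fit the rate line for one stage and derive LTT and TRD.

    ``fit_level="individual"`` regresses every individual's rate on its
    rearing temperature; ``"group_mean"`` regresses the reciprocal of each
    per-temperature mean duration (one point per temperature) — the level at
    which published summary tables of stage means are reproducible.
    """
    obs = list(observations)
    rows = _stage_durations(obs, stage, temperatures)
    n_temps = rows["temperature"].nunique()
    if n_temps < 2:
        raise ValueError(f"need >= 2 distinct temperatures, found {n_temps}")

    group_mean_dur = rows.groupby("temperature")["duration"].mean()
    if fit_level == "group_mean":
        x = group_mean_dur.index.to_numpy(dtype=float)
        y = 1.0 / group_mean_dur.to_numpy(dtype=float)
    elif fit_level == "individual":
        x = rows["temperature"].to_numpy(dtype=float)
        y = 1.0 / rows["duration"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown fit_level {fit_level!r}")

    slope, intercept, r2 = ols_line(x, y)
    if slope <= 0:
        raise ValueError(
            f"non-positive fitted slope {slope:.4g} for stage {stage!r}: "
            "development must accelerate with temperature in the linear window"
        )
    ltt = lower_threshold(slope, intercept)
    trd_mean, trd_sd, trd_sd_ind = _thermal_requirement_frame(rows, ltt)
    return StageRateModel(
        stage=stage,
        slope_a=slope,
        intercept_b=intercept,
        r_squared=r2,
        ltt=ltt,
        trd_mean=trd_mean,
        trd_sd=trd_sd,
        temperatures_used=tuple(sorted(set(map(float, rows["temperature"])))),
        fit_level=fit_level,
        trd_sd_individual=None if fit_level == "group_mean" else trd_sd_ind,
    )


def _thermal_requirement_frame(rows: pd.DataFrame, ltt: float) -> tuple[float, float, float]:
    if (rows["temperature"] <= ltt).any():
        bad = sorted(set(rows.loc[rows["temperature"] <= ltt, "temperature"]))
        raise ValueError(
            f"temperature(s) {bad} at or below the lower threshold {ltt:.2f} °C: "
            "degree-day accumulation is undefined there"
        )
    dd = rows["duration"] * (rows["temperature"] - ltt)
    group_means = dd.groupby(rows["temperature"]).mean()
    # dispersion across per-temperature group means; ddof=0 is the convention
    # used for the published "±" figures this mirrors
    trd_mean = float(group_means.mean())
    trd_sd = float(group_means.std(ddof=0)) if len(group_means) > 1 else 0.0
    trd_sd_ind = float(dd.std(ddof=1)) if len(dd) > 1 else 0.0
    return trd_mean, trd_sd, trd_sd_ind


def thermal_requirement(
    observations: Iterable[DevelopmentObservation],
    stage: str,
    ltt: float,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
) -> tuple[float, float]:
    """Thermal requirement (mean, SD) in degree-days for one stage.

    Per individual, DD = duration × (T − LTT) under constant rearing; per
    temperature the group mean DD; the returned mean/SD are taken across the
    per-temperature group means (one value per temperature in the window).
    """
    rows = _stage_durations(list(observations), stage, temperatures)
    mean, sd, _ = _thermal_requirement_frame(rows, ltt)
    return mean, sd


def fit_all_stages(
    observations: Iterable[DevelopmentObservation],
    stages: Sequence[str] = ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "larvae", "pupa", "egg_to_adult"),
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    fit_level: FitLevel = "individual",
) -> list[StageRateModel]:
    """Fit every requested stage; skips stages absent from the data."""
    obs = list(observations)
    models = []
    for stage in stages:
        try:
            models.append(fit_stage_model(obs, stage, temperatures, fit_level))
        except ValueError as exc:
            if "no observations for stage" in str(exc):
                continue
            raise
    return models


def models_to_frame(models: Iterable[StageRateModel]) -> pd.DataFrame:
    """Summary table (one row per stage) at reporting precision."""
    return pd.DataFrame([m.summary_row() for m in models])
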