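"""Synthetic rearing-experiment generator with known ground truth.

Emulates the design of the Korean rearing study so the whole pipeline is
testable offline: 30 individuals per temperature at 16/20/24/28/32/36 °C
observed at 24-h intervals, triplicate viability cohorts of 100, paired
feeding weighings with five untreated evaporation controls, and daily
min/max weather series.

Every generator is a pure function of ``(config, seed)``: the single seed in
the config fans out to fixed per-generator substreams (via
``numpy.random.SeedSequence`` spawn keys), so adding one generator never
perturbs another's draws.

Duration noise is additive Gaussian on the day scale with an optional
round-to-nearest-day and a floor of 1 day, matching the integer-day
observation process that produces small printed SDs at high temperatures.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import datasets
from .io import (
    DevelopmentObservation,
    FeedingObservation,
    TemperatureSeries,
    ViabilityRecord,
)

# substream indices: stable identity per generator
_STREAM_DEVELOPMENT = 0
_STREAM_WEATHER = 1
_STREAM_FEEDING = 2
_STREAM_VIABILITY = 3

#: Component stages whose sum defines the full development period.
_COMPONENT_STAGES = ("egg", "L1", "L2", "L3", "L4", "L5", "L6", "pupa")

# duration noise SDs (days) calibrated to the printed 24 °C dispersions
_DEFAULT_NOISE_SD = {
    "egg": 0.7, "L1": 0.7, "L2": 0.4, "L3": 0.4, "L4": 0.4, "L5": 0.4,
    "L6": 0.9, "pupa": 0.6, "egg_to_adult": 1.4,
}

# hatch probabilities at unreported temperatures are only bounded below
# (>50%); 0.55 is used as a realistic value just above that bound
_DEFAULT_HATCH_P = {16.0: 0.55, 20.0: 0.55, 24.0: 0.840, 28.0: 0.857,
                    32.0: 0.773, 36.0: 0.55}
_DEFAULT_SURVIVAL_P = {16.0: 0.310, 20.0: 0.880, 24.0: 0.973, 28.0: 0.990,
                       32.0: 0.987, 36.0: 0.453}


def _default_stage_lines() -> dict[str, tuple[float, float]]:
    return {s: datasets.published_rate_line(s) for s in _COMPONENT_STAGES}


def _default_feeding() -> dict[tuple[int, float], tuple[float, float]]:
    df = datasets.feeding_summary_published()
    return {
        (int(r.instar), float(r.temperature)): (float(r.mean_g), float(r.sd_g))
        for r in df.itertuples(index=False)
        if int(r.instar) != 0
    }


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for all generators.

    Defaults restate the study design: reported per-stage rate lines, 30
    individuals per temperature in the {20,24,28,32} °C fitting window with
    day-rounded observations, reported hatch/survival probabilities,
    reported feeding means/SDs, a 10%/day control evaporation loss, and a
    late-summer Korean weather profile.
    """

    stage_lines: dict[str, tuple[float, float]] = field(default_factory=_default_stage_lines)
    temperatures: tuple[float, ...] = datasets.FITTING_TEMPERATURES
    n_per_temperature: int = 30
    duration_noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    rounding: str = "nearest_day"  # or "none"
    hatch_p: Mapping[float, float] = field(default_factory=lambda: dict(_DEFAULT_HATCH_P))
    survival_p: Mapping[float, float] = field(default_factory=lambda: dict(_DEFAULT_SURVIVAL_P))
    n_viability_replicates: int = 3
    n_viability_exposed: int = 100
    feeding_means: Mapping[tuple[int, float], tuple[float, float]] = field(
        default_factory=_default_feeding
    )
    n_feeding_controls: int = 5
    control_evaporation_loss: float = 0.10  # fraction of leaf weight lost per day
    leaf_weight_g: float = 8.0
    balance_noise_sd: float = 0.0005  # 0.1 mg-class balance
    control_ratio_noise_sd: float = 0.005  # leaf-to-leaf evaporation spread
    weather_base: float = 26.0
    weather_amplitude: float = 6.0
    weather_period_days: float = 365.0
    weather_phase_days: float = 0.0
    diurnal_range: float = 8.0
    weather_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.rounding not in ("nearest_day", "none"):
            raise ValueError(f"rounding must be 'nearest_day' or 'none', got {self.rounding!r}")
        if self.n_per_temperature < 1:
            raise ValueError("n_per_temperature must be >= 1")
        for label, probs in (("hatch_p", self.hatch_p), ("survival_p", self.survival_p)):
            for t, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{label}[{t}] = {p} outside [0, 1]")
        if not 0.0 <= self.control_evaporation_loss < 1.0:
            raise ValueError("control_evaporation_loss must be in [0, 1)")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )

    def noise_sd(self, stage: str) -> float:
        if isinstance(self.duration_noise_sd, (int, float)):
            return float(self.duration_noise_sd)
        return float(self.duration_noise_sd.get(stage, 0.5))


def gen_development(config: SyntheticConfig) -> list[DevelopmentObservation]:
    """Draw per-individual stage durations from the configured rate lines.

    Mean duration at temperature T is ``1/(a*T + b)``; noise is additive on
    the day scale; with ``rounding="nearest_day"`` durations are rounded to
    whole days with a floor of 1 (the 24-h observation cadence). When every
    component stage (egg..pupa) is configured, an ``egg_to_adult`` row is
    derived per individual as the exact sum of its stage durations; a config
    carrying an explicit ``egg_to_adult`` line generates it directly instead.
    """
    rng = config._rng(_STREAM_DEVELOPMENT)
    for stage, (a, b) in config.stage_lines.items():
        for t in config.temperatures:
            if a * t + b <= 0:
                raise ValueError(
                    f"temperature {t} °C is at or below stage {stage!r}'s "
                    f"lower threshold {-b / a:.1f} °C"
                )

    out: list[DevelopmentObservation] = []
    sums: dict[tuple[float, int], float] = {}
    derive_total = (
        "egg_to_adult" not in config.stage_lines
        and all(s in config.stage_lines for s in _COMPONENT_STAGES)
    )
    for stage, (a, b) in config.stage_lines.items():
        for t in config.temperatures:
            mu = 1.0 / (a * t + b)
            noise = rng.normal(0.0, config.noise_sd(stage), config.n_per_temperature)
            durations = mu + noise
            if config.rounding == "nearest_day":
                durations = np.rint(durations)
            durations = np.maximum(durations, 1.0)
            for i, d in enumerate(durations):
                out.append(
                    DevelopmentObservation(
                        individual_id=f"T{t:g}-{i:03d}", stage=stage,
                        temperature=float(t), duration=float(d),
                    )
                )
                if derive_total and stage in _COMPONENT_STAGES:
                    sums[(t, i)] = sums.get((t, i), 0.0) + float(d)
    if derive_total:
        for (t, i), total in sorted(sums.items()):
            out.append(
                DevelopmentObservation(
                    individual_id=f"T{t:g}-{i:03d}", stage="egg_to_adult",
                    temperature=float(t), duration=total,
                )
            )
    return out


def gen_weather(config: SyntheticConfig, start: _dt.date, n_days: int) -> TemperatureSeries:
    """Sinusoidal seasonal daily-mean profile with diurnal offsets and noise.

    Day i has mean ``base + amplitude * sin(2π (i + phase)/period)`` plus
    Gaussian noise; t_min/t_max sit half the diurnal range below/above the
    (noisy) mean, so ``t_max - t_min`` equals the diurnal range exactly.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = config._rng(_STREAM_WEATHER)
    i = np.arange(n_days)
    mean = config.weather_base + config.weather_amplitude * np.sin(
        2.0 * math.pi * (i + config.weather_phase_days) / config.weather_period_days
    )
    mean = mean + rng.normal(0.0, config.weather_noise_sd, n_days)
    half = config.diurnal_range / 2.0
    dates = tuple(start + _dt.timedelta(days=int(k)) for k in i)
    return TemperatureSeries(
        dates, tuple(mean - half), tuple(mean + half)
    )


def gen_feeding(config: SyntheticConfig) -> tuple[list[FeedingObservation], list[str]]:
    """Paired feeding weighings with shared per-cell evaporation controls.

    For each configured (instar, temperature) cell: true intake is drawn from
    the configured mean/SD truncated at 0; the test leaf starts near the
    configured leaf weight, loses the control evaporation fraction, then the
    intake, plus balance noise. Five untreated control leaves per cell share
    the same evaporation ratio; their mean before-weight and mean
    after/before ratio give the paired control weights.

    Returns (observations, individual_ids) with ids parallel to observations
    so whole-period totals can be formed per larva.
    """
    rng = config._rng(_STREAM_FEEDING)
    retained = 1.0 - config.control_evaporation_loss
    obs: list[FeedingObservation] = []
    ids: list[str] = []
    for (instar, temp), (mean_g, sd_g) in sorted(config.feeding_means.items()):
        ctrl_before_w = rng.normal(config.leaf_weight_g, 0.3, config.n_feeding_controls)
        ctrl_ratios = np.clip(
            retained + rng.normal(0.0, config.control_ratio_noise_sd, config.n_feeding_controls),
            0.0, 1.0,
        )
        cb = float(np.mean(ctrl_before_w))
        ca = cb * float(np.mean(ctrl_ratios))
        intakes = np.maximum(rng.normal(mean_g, sd_g, config.n_per_temperature), 0.0)
        w_before = rng.normal(config.leaf_weight_g, 0.3, config.n_per_temperature)
        meas = rng.normal(0.0, config.balance_noise_sd, config.n_per_temperature)
        for i in range(config.n_per_temperature):
            w_after = w_before[i] * retained - intakes[i] + meas[i]
            if w_after <= 0:
                w_after = 1e-3  # leaf fully consumed; keep weights positive
            obs.append(
                FeedingObservation(
                    instar=int(instar), temperature=float(temp),
                    w_before=float(w_before[i]), w_after=float(w_after),
                    ctrl_before=cb, ctrl_after=ca,
                )
            )
            ids.append(f"T{temp:g}-{i:03d}")
    return obs, ids


def gen_viability(config: SyntheticConfig) -> list[ViabilityRecord]:
    """Binomial replicate draws for hatch and larval-survival endpoints."""
    rng = config._rng(_STREAM_VIABILITY)
    out: list[ViabilityRecord] = []
    for endpoint, probs in (("hatch", config.hatch_p), ("larval_survival", config.survival_p)):
        for temp in sorted(probs):
            for rep in range(1, config.n_viability_replicates + 1):
                n_succ = int(rng.binomial(config.n_viability_exposed, probs[temp]))
                out.append(
                    ViabilityRecord(
                        temperature=float(temp), replicate=rep,
                        n_exposed=config.n_viability_exposed,
                        n_succeeded=n_succ, endpoint=endpoint,
                    )
                )
    return out
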