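"""Published summary statistics for the Korean *Spodoptera frugiperda* population.

These are the reported results of the 2020-2021 Korean rearing and field-
validation study this pipeline models: per-stage development times at six
constant temperatures, the fitted rate lines with their thermal parameters,
the adult-eclosion field validation dates, leaf feeding amounts, and hatch/
survival percentages. No raw individual-level data were deposited, so these
summaries serve both as regression/degree-day inputs (stage means are
sufficient for group-mean fits) and as the calibration targets for the
synthetic-data generator.

Stage labels: ``egg``, ``L1``-``L6`` (larval instars), ``pupa``, composite
``larvae`` (L1-L6 summed) and ``egg_to_adult`` (whole development period).
"""

from __future__ import annotations

import datetime as _dt

import pandas as pd

#: Rearing temperatures used in the study (°C).
ALL_TEMPERATURES = (16.0, 20.0, 24.0, 28.0, 32.0, 36.0)

#: Temperatures retained for regression; at 16 and 36 °C survival collapses
#: and the rate response leaves the linear range.
FITTING_TEMPERATURES = (20.0, 24.0, 28.0, 32.0)

# mean ± SD development time in days, 30 individuals per temperature,
# observed at 24-h intervals
_STAGE_DURATIONS = {
    # temp: {stage: (mean, sd)}
    16.0: {"egg": (10.1, 0.7), "L1": (6.4, 0.7), "L2": (4.1, 0.6), "L3": (6.5, 0.6),
           "L4": (6.5, 0.5), "L5": (11.3, 0.8), "L6": (16.7, 0.7), "pupa": (35.3, 1.1),
           "egg_to_adult": (97.2, 1.2)},
    20.0: {"egg": (7.1, 0.2), "L1": (4.4, 0.7), "L2": (2.2, 0.4), "L3": (2.8, 0.7),
           "L4": (3.4, 0.5), "L5": (3.9, 0.7), "L6": (6.8, 0.5), "pupa": (18.9, 0.8),
           "egg_to_adult": (49.6, 1.2)},
    24.0: {"egg": (4.3, 0.7), "L1": (2.1, 0.7), "L2": (1.8, 0.4), "L3": (1.9, 0.4),
           "L4": (2.0, 0.4), "L5": (2.0, 0.4), "L6": (3.8, 0.9), "pupa": (11.8, 0.6),
           "egg_to_adult": (29.5, 1.4)},
    28.0: {"egg": (3.2, 0.5), "L1": (1.3, 0.4), "L2": (1.3, 0.5), "L3": (1.4, 0.5),
           "L4": (1.6, 0.6), "L5": (1.5, 0.6), "L6": (3.1, 0.4), "pupa": (8.7, 1.0),
           "egg_to_adult": (21.9, 1.7)},
    32.0: {"egg": (2.0, 0.3), "L1": (1.1, 0.3), "L2": (1.1, 0.2), "L3": (1.1, 0.3),
           "L4": (1.1, 0.2), "L5": (1.1, 0.3), "L6": (2.5, 0.5), "pupa": (6.3, 0.5),
           "egg_to_adult": (16.1, 1.1)},
    36.0: {"egg": (2.0, 0.2), "L1": (1.0, 0.0), "L2": (1.0, 0.0), "L3": (1.0, 0.0),
           "L4": (1.3, 0.7), "L5": (1.6, 0.8), "L6": (2.4, 0.6), "pupa": (5.9, 0.7),
           "egg_to_adult": (15.5, 0.7)},
}

# reported rate lines y = a*x + b with R², lower threshold (°C) and thermal
# requirement (degree-days, mean ± SD across temperatures)
_RATE_MODELS = {
    "egg":          (0.0289, -0.4536, 0.9626, 15.7, 34.3, 3.1),
    "L1":           (0.0590, -0.9278, 0.9686, 15.7, 17.3, 1.3),
    "L2":           (0.0428, -0.4282, 0.9915, 10.0, 23.3, 0.8),
    "L3":           (0.0466, -0.5761, 0.9989, 12.4, 21.5, 0.2),
    "L4":           (0.0531, -0.7823, 0.9782, 14.7, 18.8, 1.0),
    "L5":           (0.0533, -0.8039, 0.9947, 15.1, 18.8, 0.6),
    "L6":           (0.0211, -0.2637, 0.9838, 12.5, 47.7, 2.7),
    "larvae":       (0.0070, -0.0964, 0.9977, 13.8, 142.8, 3.5),
    "pupa":         (0.0088, -0.1256, 0.9909, 14.3, 113.4, 4.2),
    "egg_to_adult": (0.0034, -0.0490, 0.9958, 14.4, 285.3, 7.5),
}

# mean ± SD corrected leaf intake in g; instar 0 is the whole larval period
_FEEDING = {
    16.0: {1: (0.029, 0.029), 2: (0.040, 0.034), 3: (0.164, 0.106), 4: (0.372, 0.181),
           5: (1.454, 0.335), 6: (4.526, 0.746), 0: (6.610, 0.973)},
    20.0: {1: (0.026, 0.029), 2: (0.026, 0.028), 3: (0.100, 0.063), 4: (0.386, 0.154),
           5: (1.172, 0.442), 6: (4.065, 0.990), 0: (5.776, 0.829)},
    24.0: {1: (0.008, 0.007), 2: (0.028, 0.025), 3: (0.088, 0.084), 4: (0.364, 0.182),
           5: (0.867, 0.385), 6: (2.452, 0.593), 0: (3.772, 0.495)},
    28.0: {1: (0.012, 0.015), 2: (0.010, 0.010), 3: (0.104, 0.077), 4: (0.372, 0.273),
           5: (0.538, 0.237), 6: (3.640, 1.093), 0: (4.678, 1.195)},
    32.0: {1: (0.006, 0.005), 2: (0.009, 0.004), 3: (0.065, 0.059), 4: (0.255, 0.117),
           5: (0.567, 0.437), 6: (2.716, 0.869), 0: (3.617, 0.625)},
    36.0: {1: (0.027, 0.033), 2: (0.035, 0.035), 3: (0.068, 0.039), 4: (0.239, 0.106),
           5: (0.495, 0.275), 6: (2.255, 0.403), 0: (2.896, 0.449)},
}

# reported viability percentages (triplicates of 100)
_VIABILITY = {
    "hatch": {24.0: 84.0, 28.0: 85.7, 32.0: 77.3},
    "larval_survival": {16.0: 31.0, 20.0: 88.0, 24.0: 97.3, 28.0: 99.0,
                        32.0: 98.7, 36.0: 45.3},
}

# 2021 field validation: predicted adult-eclosion date per site vs observed
# eclosion counts by date
_ECLOSION_VALIDATION = {
    "Cheongju": {
        "predicted": _dt.date(2021, 9, 22),
        "observed": {_dt.date(2021, 9, 24): 12, _dt.date(2021, 9, 25): 7,
                     _dt.date(2021, 9, 26): 6},
    },
    "Boeun": {
        "predicted": _dt.date(2021, 9, 28),
        "observed": {_dt.date(2021, 9, 27): 17, _dt.date(2021, 9, 28): 6,
                     _dt.date(2021, 9, 29): 3},
    },
    "Taean": {
        "predicted": _dt.date(2021, 9, 16),
        "observed": {_dt.date(2021, 9, 20): 10, _dt.date(2021, 9, 21): 9,
                     _dt.date(2021, 9, 22): 2},
    },
}


def stage_duration_summary() -> pd.DataFrame:
    """Long table of reported stage durations: temperature, stage, mean_days, sd_days."""
    rows = [
        {"temperature": t, "stage": s, "mean_days": m, "sd_days": sd}
        for t, stages in _STAGE_DURATIONS.items()
        for s, (m, sd) in stages.items()
    ]
    return pd.DataFrame(rows)


def stage_mean_durations(stage: str, temperatures=FITTING_TEMPERATURES) -> pd.Series:
    """Reported mean durations (days) for one stage, indexed by temperature."""
    return pd.Series(
        {t: _STAGE_DURATIONS[t][stage][0] for t in temperatures}, name="mean_days"
    )


def published_rate_models() -> pd.DataFrame:
    """Reported rate lines per stage: slope_a, intercept_b, r_squared, ltt, trd_mean, trd_sd."""
    rows = [
        {"stage": s, "slope_a": a, "intercept_b": b, "r_squared": r2,
         "ltt": ltt, "trd_mean": trd, "trd_sd": sd}
        for s, (a, b, r2, ltt, trd, sd) in _RATE_MODELS.items()
    ]
    return pd.DataFrame(rows)


def published_rate_line(stage: str) -> tuple[float, float]:
    """(slope, intercept) of the reported rate line for one stage."""
    a, b, *_ = _RATE_MODELS[stage]
    return a, b


def feeding_summary_published() -> pd.DataFrame:
    """Reported corrected leaf intake: temperature, instar (0 = whole period), mean_g, sd_g."""
    rows = [
        {"temperature": t, "instar": i, "mean_g": m, "sd_g": sd}
        for t, instars in _FEEDING.items()
        for i, (m, sd) in instars.items()
    ]
    return pd.DataFrame(rows)


def viability_published() -> pd.DataFrame:
    """Reported hatch/survival percentages: endpoint, temperature, percent."""
    rows = [
        {"endpoint": e, "temperature": t, "percent": p}
        for e, temps in _VIABILITY.items()
        for t, p in temps.items()
    ]
    return pd.DataFrame(rows)


def eclosion_validation() -> dict:
    """2021 field validation per site: predicted date and observed eclosion counts."""
    return {
        site: {"predicted": d["predicted"], "observed": dict(d["observed"])}
        for site, d in _ECLOSION_VALIDATION.items()
    }
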