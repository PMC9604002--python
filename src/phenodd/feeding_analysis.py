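"""Evaporation-corrected leaf consumption per instar and per day.

Detached leaves lose water while the larva feeds, so the raw before-minus-
after weight difference overstates intake. Paired untreated control leaves
estimate the moisture-loss ratio; the corrected intake is

    intake = w_before * (ctrl_after / ctrl_before) - w_after

i.e. the weight the test leaf would have had after evaporation alone, minus
what actually remains. With no evaporation this reduces to the simple
difference; with no feeding and control-matched evaporation it is zero.
Corrected values are rounded half-up to 3 decimals (0.1 mg balance
resolution) and may be slightly negative from measurement noise; they are
retained unclipped because clipping would bias the small early-instar means.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import FeedingObservation


@dataclass(frozen=True)
class FeedingSummary:
    """Mean/SD corrected intake for one (instar, temperature) cell.

    ``instar`` is 1-6 or 0 for the whole-larval-period total (per-individual
    sum across instars). ``daily_intake`` is mean intake divided by the mean
    stage duration in days.
    """

    instar: int
    temperature: float
    n: int
    mean_intake: float
    sd_intake: float
    daily_intake: float


def corrected_intake(obs: FeedingObservation) -> float:
    """Evaporation-corrected intake (g), rounded half-up to 3 decimals."""
    if obs.ctrl_before <= 0:
        raise ValueError(f"ctrl_before must be > 0, got {obs.ctrl_before}")
    raw = obs.w_before * (obs.ctrl_after / obs.ctrl_before) - obs.w_after
    return float(Decimal(repr(raw)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def control_evaporation_ratio(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean of per-leaf after/before ratios across untreated control leaves.

    Each control leaf gives an independent estimate of the day's moisture-loss
    ratio, so the mean of ratios (not ratio of sums) is used.
    """
    ratios = [after / before for before, after in pairs]
    if not ratios:
        raise ValueError("no control pairs supplied")
    return float(np.mean(ratios))


def summarize_feeding(
    observations: Iterable[FeedingObservation],
    durations: Mapping[tuple[int, float], float] | pd.DataFrame,
    individual_ids: list | None = None,
) -> list[FeedingSummary]:
    """Per-(instar, temperature) mean/SD corrected intake plus daily rates.

    ``durations`` maps (instar, temperature) -> mean stage duration in days;
    a DataFrame with columns instar/temperature/duration is also accepted.
    ``individual_ids`` optionally identifies the larva behind each
    observation (parallel to ``observations``) so the whole-period total row
    can be computed as the per-individual sum across instars; without ids,
    observations are matched by position within each (instar, temperature)
    cell, which is correct for complete balanced cohorts.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no feeding observations supplied")
    if isinstance(durations, pd.DataFrame):
        durations = {
            (int(r.instar), float(r.temperature)): float(r.duration)
            for r in durations.itertuples(index=False)
        }

    df = pd.DataFrame(
        {
            "instar": [o.instar for o in obs],
            "temperature": [o.temperature for o in obs],
            "intake": [corrected_intake(o) for o in obs],
        }
    )
    if individual_ids is not None:
        if len(individual_ids) != len(obs):
            raise ValueError("individual_ids length mismatch")
        df["individual"] = list(individual_ids)
    else:
        df["individual"] = df.groupby(["instar", "temperature"]).cumcount()

    summaries: list[FeedingSummary] = []
    for (instar, temp), cell in df.groupby(["instar", "temperature"]):
        key = (int(instar), float(temp))
        if key not in durations:
            raise ValueError(f"missing stage duration for instar {instar} at {temp} °C")
        mean = float(cell["intake"].mean())
        sd = float(cell["intake"].std(ddof=1)) if len(cell) > 1 else 0.0
        summaries.append(
            FeedingSummary(
                instar=int(instar), temperature=float(temp), n=len(cell),
                mean_intake=mean, sd_intake=sd,
                daily_intake=mean / durations[key],
            )
        )

    # whole-larval-period total: per-individual sum across instars
    for temp, sub in df.groupby("temperature"):
        totals = sub.groupby("individual")["intake"].sum()
        total_duration = sum(
            durations[(int(i), float(temp))] for i in sorted(sub["instar"].unique())
        )
        mean = float(totals.mean())
        sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
        summaries.append(
            FeedingSummary(
                instar=0, temperature=float(temp), n=len(totals),
                mean_intake=mean, sd_intake=sd,
                daily_intake=mean / total_duration,
            )
        )
    summaries.sort(key=lambda s: (s.temperature, s.instar if s.instar else 99))
    return summaries


def summaries_to_frame(summaries: Iterable[FeedingSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "instar": "total" if s.instar == 0 else s.instar,
                "temperature": s.temperature,
                "n": s.n,
                "mean_intake_g": round(s.mean_intake, 3),
                "sd_intake_g": round(s.sd_intake, 3),
                "daily_intake_g": round(s.daily_intake, 4),
            }
        )
    return pd.DataFrame(rows)
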