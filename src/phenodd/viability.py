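"""Hatch and larval-survival proportion estimates from replicate counts.

Replicates are cohorts of eggs (hatch endpoint) or first-instar larvae
(survival endpoint) exposed at one temperature. The estimate is the mean of
per-replicate percentages — with equal cohort sizes this coincides with the
pooled percentage; with unequal sizes each replicate still counts once.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io import ViabilityRecord


def proportion_estimate(
    records: Iterable[ViabilityRecord],
    temperature: float,
    endpoint: str,
) -> tuple[float, list[float]]:
    """(mean %, per-replicate %) for one (temperature, endpoint).

    Per-replicate percentage is 100 * n_succeeded / n_exposed; the mean is
    across replicates, conventionally reported at 0.1% precision.
    """
    matching = [
        r for r in records
        if r.temperature == temperature and r.endpoint == endpoint
    ]
    if not matching:
        raise ValueError(f"no viability records for {endpoint!r} at {temperature} °C")
    per_rep = [100.0 * r.n_succeeded / r.n_exposed for r in matching]
    return float(np.mean(per_rep)), per_rep


def summarize_viability(records: Iterable[ViabilityRecord]) -> pd.DataFrame:
    """Mean percentage per (endpoint, temperature), one row each."""
    recs = list(records)
    keys = sorted({(r.endpoint, r.temperature) for r in recs})
    rows = []
    for endpoint, temp in keys:
        mean, per_rep = proportion_estimate(recs, temp, endpoint)
        rows.append(
            {
                "endpoint": endpoint,
                "temperature": temp,
                "n_replicates": len(per_rep),
                "mean_percent": round(mean, 1),
            }
        )
    return pd.DataFrame(rows)
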