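#!/usr/bin/env python
"""Fit development-rate lines and derive thermal parameters.

Two fits are reported side by side:
  (a) group-mean fits on the published per-stage mean durations — the
      reproducible route to the published regression table, and
  (b) individual-level fits on the synthetic cohorts from 01_simulate_rearing
      (run that first), showing what per-individual data add.
Writes results/rate_models_published.csv and results/rate_models_synthetic.csv.
"""

from pathlib import Path

import pandas as pd

from phenodd import (
    DevelopmentObservation,
    datasets,
    fit_all_stages,
    fit_stage_model,
    models_to_frame,
    read_development_table,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "synthetic"
STAGES = ["egg", "L1", "L2", "L3", "L4", "L5", "L6", "larvae", "pupa", "egg_to_adult"]


def published_mean_fits() -> pd.DataFrame:
    models = []
    for stage in STAGES:
        if stage == "larvae":
            # composite: one pseudo-individual per temperature carrying the
            # published instar means; the larvae fit sums them
            obs = [
                DevelopmentObservation(
                    f"m{t:g}", f"L{i}", t, datasets.stage_mean_durations(f"L{i}")[t]
                )
                for t in datasets.FITTING_TEMPERATURES
                for i in range(1, 7)
            ]
            models.append(fit_stage_model(obs, "larvae", fit_level="group_mean"))
            continue
        obs = [
            DevelopmentObservation(f"m{t:g}", stage, t, d)
            for t, d in datasets.stage_mean_durations(stage).items()
        ]
        models.append(fit_stage_model(obs, stage, fit_level="group_mean"))
    return models_to_frame(models)


def main():
    RESULTS.mkdir(exist_ok=True)
    pub = published_mean_fits()
    pub.to_csv(RESULTS / "rate_models_published.csv", index=False)
    print("group-mean fits on published stage means:")
    print(pub.to_string(index=False))

    reported = datasets.published_rate_models()
    merged = pub.merge(reported, on="stage", suffixes=("_fit", "_reported"))
    print("\nfit vs reported thresholds (°C):")
    print(merged[["stage", "ltt_fit", "ltt_reported"]].to_string(index=False))

    dev_csv = SCRATCH / "development.csv"
    if dev_csv.exists():
        obs = read_development_table(dev_csv)
        syn = models_to_frame(fit_all_stages(obs, stages=STAGES, fit_level="individual"))
        syn.to_csv(RESULTS / "rate_models_synthetic.csv", index=False)
        print("\nindividual-level fits on the synthetic cohorts:")
        print(syn.to_string(index=False))
    else:
        print("\n(no synthetic development table; run 01_simulate_rearing.py first)")


if __name__ == "__main__":
    main()
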