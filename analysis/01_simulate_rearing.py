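#!/usr/bin/env python
"""Generate the synthetic rearing experiment: all four input tables.

Emulates the study design — 30 individuals per temperature in the
{20,24,28,32} °C fitting window observed at 24-h intervals, triplicate
viability cohorts of 100 at all six temperatures, paired feeding weighings
with five untreated controls, and a 120-day late-summer daily weather
series. Writes CSVs under scratch/synthetic/.
"""

import datetime as dt
from pathlib import Path

from phenodd import (
    write_development_table,
    write_feeding_table,
    write_temperature_series,
    write_viability_table,
)
from phenodd.synthetic_data import (
    SyntheticConfig,
    gen_development,
    gen_feeding,
    gen_viability,
    gen_weather,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 20210801


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)

    dev = gen_development(cfg)
    write_development_table(dev, OUT / "development.csv")
    weather = gen_weather(cfg, dt.date(2021, 7, 1), 120)
    write_temperature_series(weather, OUT / "temperature.csv")
    feeding, _ = gen_feeding(cfg)
    write_feeding_table(feeding, OUT / "feeding.csv")
    viability = gen_viability(cfg)
    write_viability_table(viability, OUT / "viability.csv")

    print(f"seed {SEED}")
    print(f"development: {len(dev)} observations "
          f"({cfg.n_per_temperature}/temperature x {len(cfg.temperatures)} temperatures)")
    print(f"weather: {len(weather)} days from {weather.dates[0]} "
          f"(mean t_min {sum(weather.t_min)/len(weather):.1f} °C)")
    print(f"feeding: {len(feeding)} weighings; viability: {len(viability)} replicate counts")
    print(f"wrote 4 tables to {OUT}")


if __name__ == "__main__":
    main()
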