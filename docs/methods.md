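# Methods

## The model

Within an insect's favourable temperature range, development rate — the
reciprocal of stage duration — is approximately linear in rearing
temperature:

    y = a·x + b,    y = 1/duration (1/day),  x = temperature (°C)

Two biologically meaningful parameters fall out of the fitted line:

- **Lower temperature threshold (LTT)**: the x-intercept `−b/a`, the
  temperature at which the extrapolated rate reaches zero. Development is
  assumed not to proceed below it.
- **Thermal requirement (TRD)**: the degree-days a stage needs to complete.
  In the ideal linear model TRD = 1/a; empirically it is estimated from the
  rearing data as described below.

Forecasting then reduces to thermal summation: each calendar day contributes
`max(0, (t_min + t_max)/2 − LTT)` degree-days, and a stage completes on the
first day the running sum reaches its TRD. Under constant rearing conditions
the daily contribution is simply `T − LTT`.

This pipeline applies the model to *Spodoptera frugiperda* (fall armyworm),
a migratory noctuid that re-invades temperate Korea each summer and cannot
overwinter there, so outbreak timing must be forecast from the arrival of
migrants rather than from overwintering populations.

## Estimation choices

**Fitting window.** The default regression window is {20, 24, 28, 32} °C.
At 16 and 36 °C survival collapses (roughly 31% and 45% larval survival
versus ≥88% inside the window) and the rate response leaves the linear
range, so those temperatures are excluded from fitting while remaining
available for summaries. The window is configuration, not a constant.

**Fit level.** `fit_level="individual"` (the default) regresses every
individual's rate on its rearing temperature; `fit_level="group_mean"`
regresses `1/(per-temperature mean duration)`, one point per temperature.
The published regression coefficients for this system are reproducible only
at the group-mean level from the published stage means, so that level is
used wherever results are compared against published values. Note the
group-mean rate is defined as the reciprocal of the mean duration, not the
mean of reciprocals — the two differ by a Jensen gap that grows with
within-group variance.

**OLS.** The one-regressor least-squares fit is implemented directly from
the closed-form normal equations (slope = Sxy/Sxx). The test suite
cross-checks it against `scipy.stats.linregress` and against a brute-force
grid minimiser of the residual sum of squares; the library routine is never
the implementation.

**Thermal requirement.** Per individual, DD = duration × (T − LTT); per
temperature, the group mean of those values; the reported TRD mean and SD
are taken across the per-temperature group means (four values in the
default window). The dispersion uses the population SD (ddof = 0), the
convention under which the published egg-to-adult figure (285.3 ± 7.5 DD)
is reproduced; the pooled per-individual SD is additionally reported for
individual-level data. Temperatures at or below the LTT are rejected rather
than contributing zero or negative degree-days — they are outside the
linear model's domain.

**Known inconsistency in the source values.** The running-text egg-to-adult
intercept (−0.0471) disagrees with the tabulated one (−0.0490); only
−0.0490 is consistent with the tabulated threshold of 14.4 °C, so the
tabulated pair is carried in `phenodd.datasets`. Similarly the tabulated
egg intercept (−0.4536) differs in the 3rd–4th decimal from what OLS on the
published egg means gives (−0.4558); the slope agrees to 4 d.p. Both are
treated as printing/rounding artifacts of the source summaries.

## Forecasting choices

- **Day granularity, ceiling semantics.** Emergence is predicted on the day
  the cumulative sum first reaches TRD; no within-day interpolation. At
  constant temperature this equals `ceil(TRD/(T − LTT))` days, verified
  against the accumulation loop property-wise.
- **Clamping.** Daily degree-days below zero are clamped to zero (standard
  degree-day convention; matters for autumn nights near the threshold).
- **Stage chaining** (`forecast_stagewise`) starts each stage the day after
  the previous one completes and discards sub-day residual heat at the
  boundary — a conservative bias of at most one day per stage, consistent
  with the 24-h observation cadence of the data that calibrated the models.
- **Inversion.** `backcast_oviposition` walks the accumulation backwards
  from an adult-catch peak to estimate the oviposition date; it is the
  reverse application of the same summation.

## Feeding correction

Detached leaves lose water while larvae feed, so raw weight differences
overstate intake. Five untreated control leaves per cell estimate the daily
moisture-loss ratio; the corrected intake is

    intake = w_before × (ctrl_after / ctrl_before) − w_after

The control ratio is the mean of per-leaf after/before ratios (each control
leaf is an independent evaporation estimate, so mean-of-ratios rather than
ratio-of-means). Values are rounded half-up to 3 decimals, matching a
0.1 mg balance reported at 1 mg resolution. Slightly negative corrected
intakes are retained, not clipped: for first/second instars the measurement
error exceeds the true intake, and clipping would bias those means upward.
The whole-larval-period "total" row is the mean of per-individual sums
across instars, and daily intake divides mean intake by mean stage duration.

## Viability

Hatch and survival are estimated as the mean of per-replicate percentages
(triplicate cohorts of 100). With equal cohort sizes this equals the pooled
percentage; with unequal sizes each replicate still counts once, which
treats replicates — not individuals — as the unit of replication.

## Synthetic data: what it emulates and what it does not

The generator restates the rearing design as its defaults: per-stage rate
lines equal to the published fits, 30 individuals per temperature in the
fitting window, additive Gaussian duration noise on the day scale with
per-stage SDs calibrated to the published 24 °C dispersions (e.g. 0.7 d for
eggs, 1.4 d for the egg-to-adult total), rounding to whole days with a
floor of 1 day (the 24-h cadence), triplicate binomial viability cohorts of
100 at the published percentages, feeding draws at the published means/SDs
truncated at zero, a 10%/day control evaporation loss on ~8 g leaves with
0.5% leaf-to-leaf ratio spread, and a sinusoidal daily-mean weather profile
with an exact diurnal range. Hatch probabilities at 16/20/36 °C were only
reported as "above 50%"; 0.55 is used. One global seed fans out to fixed
per-generator substreams, so adding a generator never changes another's
draws.

Deliberately not emulated: temperature-dependent mortality censoring of the
development cohorts (all 30 individuals complete every stage), within-day
thermoperiod, correlated stage durations within an individual beyond the
shared line, leaf-area-based intake, and population dynamics. A green
recovery test therefore establishes that the estimators invert the stated
observation process — not that the process captures every feature of real
rearing data.

Two artifacts of the observation process are worth naming because the
synthetic world reproduces them honestly:

- **Day rounding** biases group means of short stages upward (a 1.06-day
  true mean cannot round below 1), which flattens fitted lines when many
  near-1-day stages are summed. The composite egg-to-adult cohort built by
  summing eight rounded stages therefore refits with a lower LTT and higher
  TRD than the configured truth; parameter-recovery checks use a directly
  generated egg-to-adult cohort, where the bias is below 5% of the slope.
- **Control-ratio estimation error** is shared by every larva in a feeding
  cell: with a 0.5% ratio spread over five control leaves on 8 g leaves,
  the cell-level error SD is ≈0.018 g, larger than true first-instar
  intake. This is why early-instar feeding SDs can exceed their means, in
  the synthetic output as in the published study.

## Numerical conventions

- Reporting precision mirrors the field convention: slope/intercept/R² at
  4 d.p., LTT and TRD at 1 d.p., viability at 0.1%.
- Rate-line fits require ≥2 distinct temperatures and positive slope;
  degenerate inputs raise rather than warn.
- `ols_line` defines R² = 1 when the responses are constant and exactly
  fitted (0/0 case).
- Recovery criteria for synthetic refits: LTT within ±0.5 °C and TRD within
  ±5% of the configured truth (TRD truth is the closed form 1/a), met in at
  least 90% of 100 seeds at the calibrated noise level.

## Limitations

- No nonlinear rate models (Brière, Lactin, Sharpe–Schoolfield); the upper
  developmental threshold is not estimated.
- Degree-days use the daily min/max mean, not sine/triangle integration.
- The 2021 field temperature logger series behind the published site
  predictions was never released, so the field predictions themselves
  cannot be recomputed; only the deviation scoring of the published dates
  is reproduced, with property-based checks standing in for the field run.
- The χ²-style fit statistics printed alongside the source regressions are
  not reproduced; their definition for a four-point regression is unclear,
  and fit quality is reported as R² only.
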