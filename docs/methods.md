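# Methods

## Scope and shape of the model

The package estimates the expected number of preterm births (PTBs) caused
by heatwave exposure in the last gestational week, under three climate
series: an observed-like record, a factual ensemble (natural plus
anthropogenic forcings) and a counterfactual ensemble (natural forcings
only).  The burden model is a classic attributable-fraction health impact
assessment: it needs a baseline event rate, a binary exposure indicator and
a relative risk, all resolved per grid cell and day.  Everything downstream
of exposure is linear, which the uncertainty machinery exploits.

## Heatwave detection

- Threshold: per cell, the 90th percentile (configurable) of warm-season
  (May–October) daily maximum temperatures pooled over the entire study
  period.  Quantiles interpolate linearly between order statistics; the
  convention is recorded in output metadata because different conventions
  move thresholds by a few hundredths of a degree.
- Events: maximal runs of at least two consecutive days strictly above the
  threshold.  "Exceeding" is read strictly — a day exactly at the threshold
  is not an event.  Runs are detected on the full series and may cross
  month or year boundaries; flagged days outside May–October are kept but
  accrue no burden, because baselines exist only for warm-season months.
- Exposure: day *d* is exposed if any heatwave day falls in [d−6, d]
  (window length configurable).  The window truncates at the series start.
  "At least a heatwave event in the window" is operationalized as at least
  one heatwave *day* in the window; an event need not lie wholly inside.

## Baseline and attributable burden

Monthly baselines are the four-factor product of gridded population,
provincial birth rate, provincial PTB rate and provincial monthly birth
proportion; daily baselines divide by the month length (births assumed
uniform within a month).  AF = (RR−1)/RR on exposed days, zero otherwise,
with RR = 1.19 (95% CI 1.09–1.29) by default.  Aggregates: annual
provincial/national totals, attributable PTBs per million live births
(denominator: population × birth rate summed over the region-year) and the
share of warm-season baseline PTBs.  A burden's year is the calendar year
of the delivery day.

## Scenarios and bias correction

Each simulated member is calibrated by empirical quantile mapping per cell
and calendar month: 99 paired percentile anchors fitted between the
member's factual run and the observed series over their common period,
linear interpolation between anchors and linear extrapolation beyond the
outermost two (clamping would censor the upper tail, where heatwaves
live).  The identical map corrects that member's counterfactual run; the
counterfactual is never calibrated against observations directly.
Heatwave thresholds for both scenarios come from the bias-corrected
factual series and are applied unchanged to the counterfactual — a
scenario-specific threshold would remove the attribution signal by
construction.  The anthropogenic burden is the member-wise factual minus
counterfactual difference; the annual proportion is the ratio of ensemble
means (not the mean of ratios, which is unstable when a member's factual
burden is near zero).

## Uncertainty

Only the exposure-response relationship is treated as uncertain: ln RR is
normal with mean ln 1.19 and sd = (ln 1.29 − ln 1.09)/(2 × 1.959964)
≈ 0.0430, recovered from the printed CI.  One draw applies to all cells
and days of a replicate (RR is a single national parameter).  Because the
burden is exposed-baseline × AF(RR), each draw's burden is computed
exactly rather than by re-running detection.  Observed-climate CIs are the
2.5th/97.5th percentiles over 1000 draws; scenario CIs flatten draws
across ensemble members, capturing climate-model spread as well.  The
proportion's CI uses the member spread alone, since AF cancels in the
ratio.  Baseline demographic inputs carry no uncertainty.

## Human capital

For each countable outcome the incidence among preterm births solves the
prevalence identity I_e = P_outcome·RR_outcome/(P_ptb·RR_outcome+1−P_ptb);
additional cases are nPTB·(I_e − P_outcome).  Reduced IQ is handled as
points per preterm child times the PTB count.  Costs are unit cost times
count; neonatal death is excluded from the human-capital total; sums mixing
currency years (some unit costs are in 2014 USD) are permitted but
flagged.  The model is exactly linear in nPTB, so CI bounds on the PTB
count pass through unchanged.  The bundled outcome panel
(`data/human_capital_outcomes_synthetic.csv`) is an editable fixture whose
relative risks and prevalences are synthetic placeholders; its unit costs
and 8.4 IQ points per PTB are the values implied by a published aggregate
cost table, and should be replaced with study-specific inputs for any real
analysis.

## Synthetic data

The generator produces what the analysis assumes and nothing more:

- Daily tmax = annual sinusoid (default mean 18 °C, amplitude 12 °C,
  mid-July peak) + AR(1) Gaussian noise (default sd 3 °C, lag-1
  autocorrelation 0.7 — enough persistence to create multi-day exceedance
  runs) + a linear trend (default 0.4 °C/decade) added only to the observed
  series and factual members.
- Counterfactual member *m* reuses factual member *m*'s noise stream, so
  paired members differ exactly by the injected trend; with zero trend the
  scenario difference is identically zero, which the null-attribution tests
  exploit.
- Cells are independent (no spatial covariance) because all downstream
  computation is cell-wise; provinces partition cells contiguously by
  index.
- Calendars are proleptic Gregorian; the seasonal cycle maps Feb 29 onto
  Feb 28 so the climatology repeats exactly each year.  360/365-day model
  calendars are out of scope.
- Demographics: per-cell population ≈ 10⁵ with 0.3 %/yr growth; provincial
  crude birth rate ≈ 12 per 1000 person-years; PTB prevalence grows
  geometrically (default 7 % base, 1.3 %/yr, matching the documented
  national rise); monthly birth proportions are Dirichlet-distributed
  around uniform and normalized to sum to one.
- Seeding: one master seed; substreams derive via `numpy.random.SeedSequence`
  keyed by (stream, member), making every product byte-reproducible.

What passing tests on these data show: the accounting, detection,
calibration and uncertainty logic are correct, and the attribution recovers
injected trends.  What they do not show: realism of any absolute burden
number — real temperature fields are spatially correlated, real birth
seasonality and population are far more structured, and real GCM biases
are state-dependent rather than stationary.

## Numerical choices and degenerate inputs

- Quantiles everywhere use linear interpolation; ties at the heatwave
  threshold are non-events (strict inequality).
- A degenerate (constant) simulated distribution in quantile mapping falls
  back to an additive shift.
- The anthropogenic proportion is reported missing where the factual
  burden is zero.
- Problem sizes: tests run grids of 1–6 cells over 4–30 years with 2–30
  members; the acceptance script uses 12 cells × 30 years × 5 members with
  burden accounting over the final decade — small enough to run in seconds
  while exercising every stage, and all statistics scale per-cell so cell
  count affects only Monte Carlo precision.

## Known limitations

- One national RR; no effect modification by region, humidity or
  demography, and no harvesting/displacement adjustment.
- Baseline births are spread uniformly within months; sub-monthly birth
  seasonality is ignored.
- Bias correction is stationary empirical quantile mapping; trend-preserving
  multivariate methods (e.g. ISIMIP3-style detrending) are out of scope.
- Human-capital outcome uncertainty is not propagated; only the PTB-count
  CI passes through the (linear) cascade.
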