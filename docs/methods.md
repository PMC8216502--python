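# Methods

This package couples three layers into one hazelnut yield-prediction
pipeline: (1) a statistical characterization of biennial (alternate)
bearing in annual yield series, (2) a process-based single-season
phenology/growth simulator, and (3) a random-forest regression layer fed
by the simulator's output, the on/off labels, the unit's varieties and
phenophase-windowed agro-meteorological indicators. A synthetic-data
module generates all four input sources so every stage runs and is
testable without external data.

## 1. Yield statistics

For a series of annual yields y₁…y_n (t ha⁻¹) per administrative unit:

* **Intensity index** I = Σᵢ |yᵢ − yᵢ₋₁|/(yᵢ + yᵢ₋₁) / (n−1) ∈ [0, 1]:
  0 for a constant series, 1 for perfect alternation with zero-yield off
  years. Its signed yearly form I*ᵢ = (yᵢ − yᵢ₋₁)/(yᵢ + yᵢ₋₁) satisfies
  mean(|I*|) = I identically.
* **Bienniality index** B: the percentage of years (with two
  predecessors) whose yield change reverses the sign of the previous
  change; a zero difference counts as "not alternating" (a flat step is
  not an on-off switch). B = 0 for monotone, 100 for strictly
  alternating series.
* **Significance of I**: 5,000 with-replacement bootstrap resamples of
  the yield values; the reported exceedance frequency is P(I_resampled ≥
  I_observed). Resampling destroys temporal alternation, so genuinely
  alternating series have low exceedance frequencies. Resamples that
  juxtapose two zero yields would leave one index term undefined; that
  term is dropped and the divisor reduced.
* **Negligibility threshold I₀.₀₀₁**: the yield values are order-permuted
  (without replacement) 5,000 times, the series-level I is recomputed per
  permutation, and the empirical 0.1% quantile (lower interpolation — the
  conservative choice, pushing borderline years into the
  inherit-previous-label branch) is returned. An alternative reading that
  pools the yearly |I*| values across permutations is available behind
  `pool="istar"`; the series-level reading is the default because the
  permuted statistic named in the procedure is I itself.
* **Labels**: year i is *on* if |I*ᵢ| > I₀.₀₀₁ and I*ᵢ > 0, *off* if
  |I*ᵢ| > I₀.₀₀₁ and I*ᵢ < 0, otherwise it inherits the previous year's
  label. The first year carries no data-derived label (every label is
  relative to a predecessor); a seed label can be supplied, and the
  pipeline seeds it as the opposite of a data-derived year-2 label so the
  full unit × season grid is labeled. A year is flagged *unexpected* when
  its label repeats the previous year's — including years that inherited
  their label, which literally satisfy the definition.
* **On→off reduction**: mean(off-year yields)/mean(on-year yields),
  capped at 1; passed to the simulator as the off-year fruit-partitioning
  coefficient.
* **Trend**: OLS slope of yield on year; significance from the
  Mann-Kendall test, computed as Kendall's tau of yield against time
  (scipy's exact small-sample null, tie-corrected normal approximation
  otherwise).
* **Clustering**: pairwise Pearson correlation (two-sided t
  approximation, no multiplicity correction) plus complete-linkage
  agglomerative clustering on Euclidean distances between raw yield
  vectors (scipy), whose merge heights are monotone.

## 2. Growth simulator

One season runs September 1 → August 31 (harvest), daily steps,
deterministic. The component process models are deliberately simple,
property-preserving forms; each form and its defaults follow.

**Phenology.** Chilling hours (air temperature within 0–7 °C, counted on
a symmetric 24-h sinusoid between tmin and tmax — the time-in-window has
an arcsine closed form) accumulate until the chilling requirement
(default 700 h) releases dormancy; forcing degree-days above t_base
(5 °C) then advance three parallel stage tracks: vegetative V1–V10
(dormant buds → leaf drop), catkin C1–C4, female/fruit R1–R13. Stage
thresholds are cumulative °C·d from release; the defaults place female
flowering (R4) in mid-winter, ovary development (R10, the onset of nut
growth) in April, visible nut clusters (R12) in May and immature fruit
(R13) in July under a Black Sea-like temperature course. The stage scale
is exposed in config (anchors: `fruit_onset_stage`, `frost_window_start`,
`frost_window_end`) so anchor positions can be remapped without code
changes.

**Radiation and canopy.** Missing global radiation is estimated as
extraterrestrial radiation (standard astronomical formulation) times a
clearness index rising saturatingly with the diurnal temperature range,
bounded in (0.10, 0.75]. The diffuse fraction increases with cloudiness
(1 − kt/0.75, clamped at 0.15). Interception is Beer's law over the
ground-cover fraction f_cover = crown_size²/(row_spacing × plant_spacing)
(capped at 1), with the leaf area concentrated over the covered ground
and distinct extinction coefficients for direct (0.6) and diffuse (0.7)
light. Initial LAI is linear in plant dimensions, LAI₀ = c·height·crown
(c = 0.08 m⁻²; the minimal one-constant choice given that only the
dependence on plant dimensions is specified).

**Assimilation.** Gross assimilation = amax · (1 − exp(−ε·I/amax)) ·
f_T · f_VPD: light-saturating in intercepted radiation I with initial
slope ε = 0.0022 kg DM MJ⁻¹ and ceiling amax; a Gaussian temperature
optimum f_T (t_opt 22 °C, width 12 °C); and a hyperbolic stomatal decline
f_VPD = 1/(1 + 0.25·VPD) capturing the depression of photosynthesis by
hot, dry ripening weather. VPD comes from saturation vapor pressure at
tmin/tmax and mean RH. Maintenance respiration is organ biomass ×
coefficient × Q10^((T−20)/10) (Q10 = 2; coefficients 0.010 d⁻¹ for
leaves and fruits, 0.0015–0.002 d⁻¹ for wood and roots); the remainder is
discounted by a growth-respiration fraction of 0.25. amax defaults to
0.012 kg DM m⁻² d⁻¹, set so the default orchard yields fall in the
0.8–1.4 t ha⁻¹ band typical of the emulated production regions.

**Partitioning and alternate bearing.** Net assimilate is split over
leaves/fruits/stem/branches/roots by a phase table keyed on the
female/fruit stage reached; the fruit share is zero before R10 and peaks
(0.60) during nut filling. In off years the fruit share is multiplied by
the unit's on→off reduction coefficient and the shortfall redistributed
proportionally to the other organs, preserving daily conservation
(Σ organ increments = net assimilation, to 1e-9 relative). Negative net
assimilation (respiration exceeding gross) is drawn from the non-fruit
organs in proportion to their biomass — filled nuts are not resorbed —
floored so no organ goes negative. Green LAI grows by SLA
(15 m² kg⁻¹) times the leaf increment. Yield is dry nut biomass × 10
(kg m⁻² → t ha⁻¹), no moisture model.

**Late frost.** Daily kill fraction = stage susceptibility × severity.
Susceptibility ramps linearly along the female track from 0 at female
flowering (R4) to 1 at ovary enlarging (R11) and is zero outside that
window; severity ramps linearly in tmin between a no-damage threshold
(−1 °C) and full kill (−7 °C). A season survival fraction multiplies
through (1 − kill) and scales the final yield, so the fruit-yield
trajectory is non-decreasing except at frost events.

**Calibration.** Multi-start Nelder–Mead over named parameters (flat
dotted paths into the parameter object, e.g.
`forcing_thresholds.R.9`), starting from a Latin-hypercube sample of the
bound box; candidate points are folded back into the box by reflection.
Phenology is calibrated first (objective: MAE in days between simulated
and observed stage onsets; unreached stages incur a 60-day penalty),
growth parameters second (MAE in t ha⁻¹). On jitter-free
simulator-generated observations the procedure recovers stage-onset MAE
≤ 1 day with 5 starts. Model evaluation uses a 50/50 hold-out stratified
by (unit × on/off), halves differing by at most one record per stratum.

## 3. Feature builder and ML layer

The design matrix has one row per unit × season and exactly 89
predictors: 3 variety slots + the on/off label + the simulated yield +
14 phases (R7–R13, V1–V7) × 6 indicators (min tmin, mean daily
temperature, max tmax, total precipitation, mean RH, max wind). A
phase's window runs from its onset to the next stage's onset within the
same track, half-open, clipped at August 31 — no indicator sees weather
past the prediction date. RH uses the window mean (the only aggregator
left unstated; min/avg/max are explicit only for temperature). Unreached
phases yield missing indicators, median-imputed within the training fold
only.

Resampling design: 100 splits; per split, 25% of each unit's seasons (4
of 16) are drawn without replacement into validation, and the
calibration set is a with-replacement bootstrap resample of the pooled
remainder — the reading that satisfies both "bootstrap samples with
replacement" and "each municipality exactly four times in validation"
simultaneously. The forest is 500 unpruned trees, mtry = ⌊p/3⌋, node
size 5 (the regression defaults of the randomForest ecosystem; all
exposed in config). LOOCV over the calibration rows produces the
calibration-side metrics and can optionally select mtry over a small
grid (off by default). Variable importance is %IncMSE computed on
out-of-bag samples at the forest level: OOB predictions average the
trees that did not draw a sample, and permuting one predictor column
gives %IncMSE = 100·(MSE_perm − MSE_oob)/MSE_oob; the reported ranking
is the median across splits. Per-row percent errors are
100·(pred − obs)/obs (positive = overestimation; note CRM below keeps
the opposite sign convention), medianed over the splits where the row
was validated, with the shares of cells within ±10% and ±20% attached.

Evaluation metrics: MAE; RRMSE = 100·RMSE/mean(obs); R² = squared
Pearson correlation; Nash–Sutcliffe EF; CRM = (Σobs − Σpred)/Σobs, so
negative CRM means overestimation. When predictions are the least-squares
line through the observations, EF = R² — used as a cross-check. Both R²
and EF are undefined (NaN, flagged) against zero-variance observations.

## 4. Synthetic study conditions

The default bundle mirrors the study dimensions: 7 units × 16 seasons
(2004–2019). Unit means (0.64–1.30 t ha⁻¹) and bienniality amplitudes
(0.16–0.31) follow the printed per-region ranges, with the western group
higher-yielding and milder and the eastern group more strongly
alternating; yield noise is Gaussian (sd 0.05 t ha⁻¹, the low end of the
printed per-unit standard deviations), floored at 0.01 so the intensity
index stays defined. The two groups alternate in opposite phase, which
lets the correlation/clustering stage separate them structurally. One
shock (2014, multiplier 0.35, eastern units) flips an on year to an
unexpected off year and coincides with an injected −5 °C frost on
April 6, 2014, so the frost-damage branch is exercised. Weather is a
seasonal sinusoid (annual mean 14 °C, amplitude 9 °C, minimum
mid-January, unit offsets ±0.7 °C) with 2 °C daily noise, an 8 °C mean
diurnal range, wet-day Bernoulli(0.4)/exponential(6 mm) precipitation,
bounded RH and wind draws, at latitude 41°.

What the generator does *not* emulate: spatial weather gradients within
a unit (one series per unit, not a 0.5° grid), autocorrelated weather
and multi-day frost spells, non-Gaussian yield errors, management or
disease effects, and any statistical resemblance to the actual Turkish
series. Passing tests therefore demonstrate internal correctness —
parameter recovery, conservation, monotonicity, labeling and ranking
behavior — not predictive skill on real data.

## 5. Numerical choices and problem sizes

* All resampling is seeded; one `numpy` Generator per operation call;
  the pipeline carries explicit per-stage seeds and echoes them in the
  manifest. Simulation and the ML layer are bit-reproducible given
  inputs and seeds.
* Quantile convention for I₀.₀₀₁: lower interpolation (conservative).
* Nelder–Mead: 200 iterations per start, xatol 1e-4; bounds by
  reflection; degenerate (point) bounds return that point.
* The test suite runs the resampling study at its full size (100 splits,
  500 trees) where the property under test concerns the resampling
  distribution, and at reduced sizes (3–10 splits, 30–100 trees,
  300–500 bootstrap/permutation draws) for smoke and determinism tests.
  LOOCV is exercised at small n; the full 100-split × 84-row LOOCV run
  is available through the CLI but not exercised in the default test
  run.

## 6. Known limitations

* The component process models are simplified stand-ins specified by
  their qualitative properties (saturation, optimum, monotone decline);
  absolute simulated yields depend on defaults chosen to land in a
  realistic band, not on calibration against field data.
* The stage scale (V/C/R enumerations and anchor positions) is a
  package-defined convention, configurable but not validated against an
  observational protocol.
* The first season's on/off label is an alternation-based convention,
  not data.
* No soil water/nitrogen balance, pests/diseases, variety-specific
  parameters, multi-year carry-over physiology, or within-season
  forecasting; cross-unit weather is generated independently per unit.
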