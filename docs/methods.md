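# Methods

## Scope and data model

The package analyses six-sensor MOS e-nose acquisitions of chamber
headspace from a growing plant, labelled by day-after-sowing (DAS 11–32),
daylight period (morning 09:00–10:00, afternoon 15:30–16:30, half-open
windows, naive local time) and irrigation phase (irrigated through
DAS 20, stressed afterwards).  One acquisition records resistance at
1 Hz for 240 s; a 300 s acquisition cycle includes the purge and is kept
as metadata only.  Chamber environment (internal/external temperature,
RH, CO₂; external luminosity) is logged every five minutes; a session's
environmental snapshot is the mean of the samples inside its window.

## Sensitivity and baseline

Sensitivity is S(%) = 100·(R − R₀)/R₀.  The instrument does not expose
its baseline estimator, so R₀ defaults to the mean of the first five
samples — robust to single-sample noise — with a `first-sample`
alternative.  The per-sensor scalar response is the *signed* value of
largest |S| (ties to the earliest sample), so resistance-drop and
resistance-rise chemistries are handled uniformly.  Traces with sampling
gaps are rejected rather than interpolated: at 1 Hz over 240 s a gap
indicates a corrupt record, and interpolation would bias the peak.

## Radar area

Aₙ = ½·sin(2π/n)·Σ xᵢ₋₁xᵢ with cyclic closure x₀ := xₙ, which is exactly
the shoelace area of the polygon with vertices at radii xᵢ on n equally
spaced spokes (n ≥ 3).  The feature pipeline feeds it peak *magnitudes*,
so mixed-sign responses cannot produce a negative area; signed peaks stay
available as separate features.  Properties (rotation/reversal
invariance, quadratic scaling, agreement with an independently coded
shoelace oracle to 1e-9) are enforced in the test suite.

## Trend ("regression") features

The published tree names attributes like `regression_max_sensor 6`
without defining their construction.  We define them as the OLS slope of
the named quantity (peak |S| per sensor, internal temperature) against
DAS over a trailing window of sessions of the same daylight period
(default 5, minimum 2 points; the first session of each period has no
trend and its row is dropped before classification).  The slope is
scaled by √Sxx, the square root of the window's design variance: the OLS
slope of iid noise has variance σ²/Sxx, so the scaled feature has a
sampling variance independent of how many days the window holds.
Without this, short early windows make the feature's own noise level a
clock — it encodes elapsed time, and since phase is a deterministic
function of DAS in this design, a classifier could read the label out of
pure noise.  With it, a no-effect configuration is genuinely
uninformative, which is what the chance-level null check requires.

## Classifier

* **Learner** — C4.5-style recursive partitioning: candidate thresholds
  are midpoints between consecutive distinct sorted values; the split
  maximising the information-gain ratio wins, with ties broken by
  feature name then threshold so training is invariant to row order.
  Stopping: purity, `max_depth` (default 5), or `min_leaf` (default 5)
  rows per side.  Leaf ties resolve to "irrigated": calling a watered
  plant stressed is the less harmful error, so ambiguity must never
  hide true stress.  With unbounded depth and unit leaves the learner
  attains the exhaustive-search optimum on generic real-valued data
  (every impure node with distinct values admits a positive-gain split);
  the suite verifies equality with a closed-form brute-force oracle —
  the majority count within groups of identical feature vectors — on
  random datasets, plus a scikit-learn cross-check.  At small *fixed*
  depths a greedy gain-ratio tree is not accuracy-optimal in general;
  the oracle equivalence is therefore checked at the depth-unbounded
  optimum, where it is exact.
* **Fixed reference tree** — the published three-split tree
  (`regression_max_sensor_6 ≤ 0.829849`, then `max_sensor_6 ≤ 0.315273`
  or `regression_temperature_int ≤ 0.714568`) ships verbatim for routing
  studies; its thresholds live on min-max-normalised [0,1] features.
* **KNN baseline** — Euclidean majority vote on normalised features;
  vote ties break by smaller within-neighbourhood distance sum, then
  toward "irrigated".
* **Evaluation** — grouped leave-plants-out (default: train 9 plants,
  test 3) so replicates of one plant never straddle the split;
  row-normalised 2×2 confusion matrices (true class in rows) and overall
  accuracy.  Min-max normalisation stats are fitted on training plants
  only and clipped on the test side; degenerate features map to 0.

## Synthetic generator

* **Sensor kinetics** — first-order relaxation from R₀ toward
  R₀(1 − d), d = g·c/(1 + g·c), time constant 25 s after a 10 s
  transport delay (so the default baseline window is pre-response),
  multiplicative Gaussian instrument noise of 0.02 % (resistance
  measurement on this class of instrument is quiet; the dominant
  variability is biological/ambient — and it keeps the extreme-value
  bias of the per-trace peak ≲0.05 S-units, so quadrature calibration
  is exact to well within the acceptance bands).  Baselines drift
  0.05 %/day; the sensitivity transform cancels drift by construction.
* **Emission model** — per-channel concentration
  c = base · e^(growth·ΔDAS) · afternoon^[pm] · stress^[stressed] · weather,
  with a session-level lognormal weather factor (σ = 0.2, shared across
  channels and coupled to the logged luminosity draw) and independent
  per-replicate channel noise (σ = 0.05).  σ = 0.2 puts the
  session-to-session peak SD near 4 %, the order of the reference
  study's reported ±3.3–4.9 scatter.
* **Calibration** — defaults are solved, not tuned: Gauss–Hermite
  integration of the saturating response over the lognormal noise gives
  the phase-mean peak in closed form, and Brent root-finding inverts it
  per channel so that the irrigated/stressed phase means equal the
  configured targets (−27.97/−28.62 % for P10/1, −28.30/−28.88 % for
  P40/1 — the reference experiment's printed values; the four unprinted
  channels get plausible smaller magnitudes, since those two sensors
  showed the strongest response).  `stress_effect` is per-channel
  because the saturating map sends one concentration multiplier to
  different sensitivity shifts at different operating points; a scalar
  cannot satisfy all four targets.  `EmissionParams.scaled_stress(λ)`
  exponentiates the multipliers: λ=0 is the exact null, λ=1 the
  calibrated default, λ>1 a stronger stress.
* **Growth trend** — default 0.  A common growth trend is perfectly
  confounded with the irrigation phase in this single-schedule design
  (phase is a function of DAS), so any nonzero default would let a
  classifier score above chance with no stress effect at all.  The
  parameter exists for sensitivity studies; the confound is a property
  of the experimental design being emulated, not of the generator.
* **Environment** — period-dependent diurnal levels with per-session
  Gaussian day effects and within-window jitter; the chamber runs warmer
  than the laboratory (+2 °C morning, +3.5 °C afternoon).  Internal CO₂
  sits ~195 ppm below external (canopy uptake) and RH above external
  (transpiration).  Both couple to the *same* stress multipliers as the
  gas channels through an activity factor (exponent 1.5, a secondary
  signal of ~1σ — the e-nose channels remain the primary evidence, and
  a null emission model nulls the environment exactly).  Uptake rises
  under stress, so internal CO₂ falls after irrigation stops, matching
  the reference study's description.  Each plant is an independent
  chamber run with its own weather — the reference study's twelve
  soybeans came from separate runs over three years — which is also what
  keeps day signatures from leaking across a grouped train/test split.
* **Empty-chamber baseline mode** — clipped diurnal sinusoids keep
  internal temperature in 23–27 °C, RH in 16–25 % and CO₂ in
  250–270 ppm, so QC ranges never exceed 4.0 °C / 9.0 % / 20 ppm by
  construction.
* **Randomness** — one root seed; per-(plant, DAS, period) generators
  derive from `SeedSequence` spawn keys, so any subset of the experiment
  regenerates identically and byte-identical outputs follow from equal
  configs.

## Soil bookkeeping

Gravimetric moisture uses a dry-mass basis, θw = 100·(wet − dry)/dry —
the basis on which the study's own oven-dry example (127.25 g → 118.81 g
= 7.1 %) reconciles; a wet basis would give 6.6 %.  Bulk density is
mass/volume (4 758 g / 8 090 cm³ = 0.59 g/cm³).  Reporting precision:
one decimal for percentages, two for g/cm³.

## Problem sizes and statistical checks

The calibration checks run the full 12-plant schedule (528 sessions) and
compare empirical per-channel peak means and SDs against the
quadrature-implied moments within 2 standard errors (the SD band uses
the kurtosis-adjusted SE of a sample SD).  The pipeline-level properties
use 6-plant runs (264 sessions each, ~84 held-out rows): the null
configuration's mean held-out accuracy over 20 seeds must lie in
[40 %, 60 %], and median accuracy over 10 seeds must increase strictly
across stress scales λ = 0, 1, 2.  Note the held-out classes are mildly
imbalanced (9 irrigated vs 12 stressed days survive the trend-feature
window per period), so "chance" sits slightly above 50 %.

## What the synthetic results do and do not show

Passing tests demonstrate that the pipeline is internally consistent:
it recovers configured effects at the configured noise, reports chance
when no effect exists, and responds monotonically to effect size.  They
do not validate the biology — real VOC emission under drought is not a
per-channel multiplicative shift, real sensors drift nonlinearly and
cross-react with humidity, and real weather is autocorrelated across
days, none of which the generator emulates.  The reference experiment's
headline held-out accuracy depends on its unreleased raw data and is
deliberately not a target; the default synthetic configuration lands
near 70 % precisely because the calibrated effect is subtle.

## Known limitations

* The trend-feature construction behind the published attribute names is
  an assumption (documented above); other constructions would change the
  fixed tree's inputs.
* The learner implements depth/min-leaf/purity stopping only — no
  error-based pruning, no missing-value handling, binary classes only.
* The generator's "500 gas samples from 12 soybeans" bookkeeping cannot
  be reconciled exactly with a single 22-day schedule; counts are
  configurable instead (12 plants × 22 DAS × 2 sessions = 528).
* Environmental covariates are conditionally independent given the
  session; real microclimate series carry within-window autocorrelation
  beyond the jitter modelled here.
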