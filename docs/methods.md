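# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the test suite does and does not establish.

## Oxygen physics

Solubility uses the Benson–Krause freshwater equilibrium fit

    ln C* = −139.34411 + 1.575701e5/T − 6.642308e7/T² + 1.2438e10/T³ − 8.621949e11/T⁴

(T in kelvin, C* in mg/L at 1 atm moist air, zero salinity), scaled by
the standard pressure correction built from the water-vapour pressure
and the θ polynomial — the convention used by the USGS solubility
tables, which the curve matches to ±0.02 mg/L over 0–40 °C.  The
formulation is a pluggable function: any alternative solubility law
with the same `(temperature_c, pressure_atm) → mg/L` signature can be
substituted.  Valid temperature range is −2…45 °C; when a forcing
series contains colder air (high-latitude winters) the callers clip to
this range before computing DOsol, on the argument that surface water
under ice sits near 0 °C regardless of air temperature.  Pressure
defaults to the international-standard-atmosphere barometric formula of
elevation when no pressure field is supplied.

The saturation departure is reported as signed percent,
`DO SP = 100·(DO − DOsol)/DOsol` (positive = supersaturation); the
percent-of-saturation convention (`100·DO/DOsol`) is available behind a
separate function for users who prefer it.

## Water colour

FAI and the hue angle follow the band-centre constants 645/859/1240 nm
and the printed tristimulus coefficients exactly.  Two conventions were
genuinely ambiguous and are fixed as documented constants:

* the hue angle's two-argument arctangent takes `(x − 0.33)` as
  numerator and `(y − 0.33)` as denominator, plus 180°, giving
  a ∈ (0, 360]; the white point is 0.33 exactly (not 1/3);
* NDWI is `(green − NIR)/(green + NIR)` with the per-scene threshold
  from Otsu histogram splitting; a constant NDWI field has no split and
  yields an all-true mask with a warning.

The 3×3 window CV gate uses the population SD (divide by 9): the nine
pixels are the entire neighbourhood, not a sample; the pass rule is the
strict inequality CV < 10%.  Mask refinement applies, in order, the
optical-depth cutoff (OD < 20 removed), the occurrence cutoff
(> 70% kept), one-pixel binary erosion and connected-component
filtering (< 4 pixels dropped), both with 4-connectivity —
conservative shoreline removal.  Optical depth arrives as a precomputed
field; no inherent-optical-properties inversion is performed here.

## DO regression

Matchups pair an in situ surface observation with the nearest climate
record within 1 hour and the nearest (CV-gated) reflectance sample
within 2 days; ties on the absolute gap resolve to the earlier record
(deterministic, auditable).  Wind speed enters as √(u² + v²).  Features
are standardised then min–max rescaled to [0, 1], fitted on training
rows only; test rows outside the training range scale outside [0, 1]
and are not clipped (tree ensembles are unaffected, and clipping would
silently hide distribution shift).  A zero-variance feature pins at 0.5
with a warning.

The production model is a random forest; a gradient-boosting
alternative is available through the same `fit_model(model="gbm")`
surface for comparison runs.  The default hyperparameter grid is
n_trees {200, 500} × depth {10, 20, ∞} × min-leaf {1, 5} with 3-fold
cross-validation; the demo pipeline uses a single-point grid
(100 trees, depth 20, min-leaf 2) because a 12-point CV search on a
~20k-row desk-scale table spends minutes to choose between statistically
indistinguishable ensembles.  `evaluate` refuses test rows whose ids
overlap the training ids (leakage guard); rows with a zero target are
excluded from MRE with their count reported.

## Trends

Summer is Jul–Sep in the northern hemisphere and Jan–Mar in the
southern; annual values are summer medians (robust to outliers).
Slopes are Theil–Sen (median of pairwise slopes, via
`scipy.stats.theilslopes`) reported per decade.  Mann–Kendall uses the
tie-corrected variance and a continuity-corrected normal approximation,
switching to the exact permutation null of S for n ≤ 10 without ties
(cheap where the normal approximation is weakest).  α defaults to 0.05,
two-sided.  No multiple-testing control is applied across lakes;
results are reported per lake.  No autocorrelation pre-whitening is
performed (a known extension).

## Heatwaves

The baseline climatology assigns each calendar day (1–365; Feb 29
shares slot 59 with Feb 28, keeping arrays fixed-length) the mean and
90th percentile of that day's values over 1970–1999.  The percentile
rule is linear interpolation between order statistics — stated
explicitly because small-sample percentiles are rule-sensitive.  The
default pools strictly per calendar day; an optional ±k-day pooling
window (common in the heatwave literature) is available via
`window_halfwidth`.  An event is a maximal run of days with
T strictly above the day-specific threshold, of length ≥ 5; runs may
cross year boundaries; shorter runs are heat spikes, not events.

The instantaneous impact predicts DO twice per heatwave day — actual
temperature vs that day's climatological mean, all other features
unchanged — and reports the signed percent difference normalised by the
counterfactual.  The mean intensity is day-weighted by default
(event-weighted available); the maximum is the value of largest
magnitude with sign preserved.  The long-term impact compares the
multi-year mean DO between the actual series and a scenario in which
every heatwave day's temperature is replaced by the day-specific
climatological mean — the same reference temperature as the
instantaneous counterfactual, which keeps the two statistics coherent.

## Attribution

Per lake, ≥ 10 annual values of (DO, DOsol, FAI, T, wind, pressure) are
standardised to mean 0, SD 1, and three least-squares sub-models are
fitted piecewise: `DOsol ~ T + wind + pressure`, `FAI ~ T`,
`DO ~ DOsol + FAI`.  Contribution percentages are 100 × the mean
standardized coefficient across lakes — the simplest aggregation
consistent with standardized path coefficients measuring strength and
direction; it is a documented, pluggable choice, and the cohort summary
also reports per-path direction counts with |coef| < 0.05 classed as
negligible.  No fit indices or latent variables are computed.

## Stress and projection

Stress frequency is the percentage of time steps (whatever resolution
the series carries — recorded in the output) strictly below
6.0 mg/L; a stressed lake has an annual mean below 6.0.  Projection
holds FAI and hue angle at their trailing 5-year means (they cannot be
observed in the future), feeds per-member scenario forcing through the
fitted model, and summarises the ensemble as mean ± 2 SD per time step
with per-member and ensemble trends per decade.  No bias correction or
downscaling is applied; scenario forcing is user-supplied (the
synthetic generator emits mock members by perturbing the warming rate
and noise seed).

## The synthetic generator

The generator defines the study conditions; all downstream claims are
relative to it.

* **Cohort**: lakes ≥ 10 km², latitudes cycled over NH-temperate
  (30–65°), SH-temperate (−55…−30°) and tropical (±29°) bands so every
  band is populated; elevations 0–5000 m (gamma-distributed, mostly
  low); areas lognormal above 10 km².
* **Climate**: daily temperature = latitude/elevation-dependent
  baseline + hemisphere-phased seasonal cosine + linear warming
  (default 0.3 °C/decade) + AR(1) noise with coefficient 0.7
  (persistence makes percentile-exceedance runs occur naturally) +
  injected heatwave blocks (Poisson rate 2/yr, ≥5 days, +5 °C),
  injected only after the baseline period so the climatology stays
  clean.  Pressure follows the barometric formula with small AR(1)
  wobble; solar/thermal/precipitation/wind carry plausible seasonality
  and noise but no weather-system structure.
* **Trophic state and reflectance**: a latent trophic state (per-lake
  baseline, summer bloom, slow trend, AR(1) wobble) drives the NIR band
  above the red–SWIR baseline by 0.02 reflectance units per trophic
  unit, so downstream FAI recovers the latent state; green rises and
  blue falls with trophic state, moving the hue angle.  Sampling is
  sparse Bernoulli at ~28.5 samples/year.
* **True DO**: `DOsol(T, P) · (1 + g) + N(0, 0.3 mg/L)` with
  `g = 0.15·tanh(trophic)·solar/solar_max` — bounded supersaturation of
  at most 15%, increasing in trophic state and light.  Setting `g = 0`
  and noise off gives the pure-saturation limit used by several exact
  tests.
* **Observations**: surveys at ~12/year, local noon ± 30 min (so the
  1-hour climate window is exercised), meter error 0.3 mg/L — a
  representative accuracy for field optical DO sensors; the value is
  configurable.
* **Path cohorts** (`make_path_cohort`): annual standardized driver →
  response chains built with exactly unit population variance, so the
  generating weights are the population standardized path coefficients
  being estimated.

What the generator does **not** emulate: cloud and quality-flag
structure, spatial pixel structure within a lake (series are per-lake
points; the 3×3 CV gate is exercised on window fixtures), atmospheric
correction error, observation gaps in climate forcing, ENSO-like
interannual modes, and ice phenology beyond the sub-zero masking
convention.  Passing tests therefore demonstrate internal correctness
and recoverability under known structure, not skill on real satellite
matchups.

## Problem sizes and reproducibility

The demo configuration (200 lakes, 2003–2023, seed 42) runs the full
pipeline in about a minute on one CPU and is byte-reproducible:
identical config + seed gives identical file digests, including the
serialised model.  Recovery experiments use 500 lakes (trend), 200
replicates (paths), ~30,000 matchups (model skill), 1,000–2,000 series
(detector and test oracles).  All randomness flows from
`numpy.random.default_rng` seeded per (seed, component, lake), so any
stage can be regenerated in isolation.

## Known limitations

* The regression extrapolates poorly beyond its training temperature
  range (a property of tree ensembles); projected declines under strong
  warming are therefore conservative, and the scenario-contrast checks
  use the closed-form solubility predictor instead.
* Mann–Kendall p-values assume serially independent annual values;
  summer-median aggregation reduces but does not remove autocorrelation.
* The attribution sub-models are linear in standardized annual means;
  nonlinear temperature–solubility curvature within a year is absorbed
  into the coefficients.
* Heatwave detection uses air temperature as the forcing proxy, not
  lake surface water temperature.
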