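# lakedo

Reconstruction and climate attribution of **lake surface dissolved oxygen
(DO)** from daily climate forcing, satellite water-colour indices and
geographic factors — with the full analysis chain exercised on a
synthetic-lake generator whose ground truth is known exactly.

Surface deoxygenation of lakes is driven largely by warming (through the
temperature dependence of oxygen solubility) and modulated by
eutrophication (through photosynthesis and respiration).  `lakedo`
implements, as a tested and reusable pipeline:

1. **Water-colour features** — the floating algae index
   `FAI = R(NIR) − R(red) − (R(SWIR) − R(red))·(859−645)/(1240−645)`
   and the CIE chromaticity hue angle `a′ = a − Δa(a/100)` with the
   standard tristimulus transform, plus NDWI/Otsu water masking, the
   optical-depth and occurrence filters, one-pixel erosion and the 3×3
   window coefficient-of-variation gate.
2. **Oxygen physics** — Benson–Krause freshwater solubility `DOsol(T, P)`
   with the barometric pressure correction, and the saturation departure
   `DO SP = 100·(DO − DOsol)/DOsol`.
3. **DO regression** — matchups of in situ DO with climate (±1 h) and
   reflectance (±2 d) records; standardise-then-minmax feature scaling;
   a random-forest regressor (gradient boosting retained for
   comparison) over ten features: air temperature, pressure, solar and
   thermal radiation, precipitation, wind speed, FAI, hue angle,
   elevation and absolute latitude.
4. **Trends** — summer-only annual medians (Jul–Sep north, Jan–Mar
   south), Theil–Sen slopes per decade, Mann–Kendall significance with
   tie correction.
5. **Heatwaves** — events of ≥5 consecutive days above the day-specific
   90th percentile of a 1970–1999 baseline climatology; counterfactual
   *influence intensity* `100·(DO_actual − DO_clim)/DO_clim` on heatwave
   days and the long-term impact of removing heatwaves.
6. **Attribution** — per-lake standardized path models
   (`DOsol ~ T + wind + pressure`, `FAI ~ T`, `DO ~ DOsol + FAI`) and
   cohort mean contributions.
7. **Stress & projection** — stress frequency below 6.0 mg/L, stressed-
   lake counts, and scenario-ensemble DO projection with water-colour
   features frozen at their recent 5-year means.

## Worked example

```python
from lakedo import PipelineConfig, SyntheticConfig, run_end_to_end

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_lakes=200),  # 2003-2023 study period
    seed=42,
    outdir="demo_run",
)
manifest = run_end_to_end(cfg)
for k in ("mean_do_mg_l", "median_do_trend_mg_l_per_decade",
          "mean_influence_intensity_pct", "mean_longterm_impact_pct"):
    print(k, round(manifest["summary"][k], 3))
```

prints (seed 42):

```
mean_do_mg_l 10.814
median_do_trend_mg_l_per_decade -0.016
mean_influence_intensity_pct -7.97
mean_longterm_impact_pct -0.932
```

Reading these numbers: the synthetic cohort's reconstructed surface DO
averages 10.8 mg/L; the median lake loses DO slowly (the tropics-heavy
cohort includes lakes where eutrophication-driven supersaturation
offsets solubility loss); during heatwave days the model predicts DO
7.97% below what the same model predicts at climatological-mean
temperature (deoxygenation); and removing heatwaves entirely would
change the 21-year mean DO by under 1% — heatwaves act fast but
contribute little to the long-term mean.

The run directory contains every intermediate table as CSV (lakes,
matchups, predictions with DOsol/DO SP, per-lake trends, heatwave
events and impacts, path coefficients, stress counts, projections) and
a `manifest.json` whose config hash and per-file digests make reruns
byte-reproducible.

The same pipeline is scriptable from the shell:

```bash
lakedo run-all --config config.yaml --seed 42
lakedo trend --in annual.csv --alpha 0.05
lakedo heatwaves --temps t.csv --baseline 1970:1999 --min-duration 5
```

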