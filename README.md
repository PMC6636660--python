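# acdpipe

Plot-level estimation of forest **aboveground carbon density (ACD, Mg C
ha⁻¹)** from airborne discrete-return LiDAR, for coniferous stands measured
with the area-based approach. The package targets the workflow used in
LiDAR-assisted carbon accounting of pure spruce (*Picea crassifolia*)
forest: square 20 m × 20 m calibration plots, species-specific component
allometry, canopy-height-model (CHM) metrics, and wall-to-wall mapping on a
fishnet grid.

## The models

Field plots provide the response. Per-tree aboveground biomass (kg) is the
sum of four power-law components in the combined size variable D²H
(D = DBH, cm; H = height, m):

    stem    = 0.0478 (D²H)^0.8665      branch = 0.0061 (D²H)^0.8905
    foliage = 0.2650 (D²H)^0.4701      fruit  = 0.0342 (D²H)^0.5779

Plot AGB (Mg ha⁻¹) is the per-tree sum scaled by plot area, and
ACD = 0.5034 · AGB (locally determined carbon fraction). Plot structure
metrics are arithmetic mean height AvgH, Lorey's height
LorH = Σ BAᵢHᵢ / Σ BAᵢ, and basal area BA (m² ha⁻¹).

LiDAR provides the predictors. After ground classification, DEM
construction and height normalization, the CHM is rasterized (mean return
height per pixel, IDW gap fill) and each plot gets its **top-of-canopy
height** TCH (mean of the plot's CHM pixels — 400 pixels for a 20 m plot at
1 m resolution), height percentiles h25…h95, density metrics d25…d95 and
canopy cover CC. Four model families are fitted by OLS after natural-log
transformation:

* power model ACD = a·Xᵇ for X ∈ {AvgH, LorH, BA, TCH}
* linear link BA′ = a + b·TCH
* daisy chain ACD = a·BA′^b1·TCH^b2
* percentile regression ln ACD = β₀ + Σ βⱼ ln(metricⱼ), reduced by
  backward elimination

with log-scale R², back-transformed RMSE and seeded k-fold cross-validation.
Fitted models are applied wall-to-wall on a 20 m fishnet to produce ACD maps,
map summaries (mean, max, total carbon stock) and map comparisons, plus a
sensitivity analysis of the TCH model to CHM pixel size (1–10 m).

Because real campaign data are not redistributable, the package ships a
first-class synthetic module: spruce-like stands (truncated-Weibull DBH,
height curve with lognormal scatter, per-plot site effects, a sparse veteran
overstory, conical crowns) and a discrete-return LiDAR simulator (jittered
pulse grid at 3.43 pulses/m², first-surface returns, canopy-penetrating
ground echoes, ranging noise, gross outliers) with ground-truth labels, so
the entire chain is testable end to end.

## Worked example

```python
from acdpipe.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1), "out/")
```

writes `out/report.txt` (plus JSON and CSV artifacts):

```
ACD pipeline run (seed 1)
trees simulated: 5962; returns: 175928

model fits (log-scale R^2 / cv R^2 / back-transformed RMSE):
  daisy_chain     r2=0.8949 cv_r2=0.8859 rmse= 15.1480
  percentile_mlr  r2=0.9191 cv_r2=0.8994 rmse= 13.3147
  power_avgh      r2=0.7963 cv_r2=0.7593 rmse= 21.8106
  power_ba        r2=0.9891 cv_r2=0.9884 rmse=  4.7921
  power_lorh      r2=0.6440 cv_r2=0.5540 rmse= 29.8847
  power_tch       r2=0.8949 cv_r2=0.8868 rmse= 15.1091
map_tch: mean=114.41 max=261.64 Mg C/ha, total=457.64 Mg (100/100 cells)
map_mlr: mean=114.65 max=270.62 Mg C/ha, total=458.61 Mg (100/100 cells)
relative total difference: 0.21%
pixel-size sensitivity (pixel m: R^2):
   1.0: 0.8949
   ...
  10.0: 0.8461
```

Reading the output: basal area is by far the strongest single predictor of
carbon density (R² ≈ 0.99 here; its exponent is near 1, i.e. ACD is almost
proportional to BA), plot-mean heights are much weaker, and the
LiDAR-measurable TCH sits in between. The daisy-chain model (TCH → BA′ →
ACD) adds essentially nothing over the direct TCH power model, the two
wall-to-wall maps agree to a fraction of a percent in total stock, and the
TCH model degrades as CHM pixels coarsen.

The same stages are available from a shell:

```bash
acd-pipeline simulate --seed 1 --n-plots 94 --out out/
acd-pipeline inventory out/stand_truth.csv --out out/summaries.csv
acd-pipeline metrics out/points.tsv --pixel-size 1 --out out/metrics.csv
acd-pipeline run --config run.yaml --out out/
```

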