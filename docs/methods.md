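# Methods

## Scope and data model

The package estimates plot-level aboveground carbon density (ACD) of a pure
coniferous stand from airborne discrete-return LiDAR using the area-based
approach, and maps it wall-to-wall. Its data model mirrors a field campaign:
a tree table (DBH ≥ 5 cm, height, position), classified LiDAR returns, a DEM
and CHM, a per-plot table of LiDAR predictors joined to field responses, and
fitted model objects that can be pushed over a fishnet grid.

## Field response

Per-tree biomass uses species-specific component power laws in D²H (stem,
branch, foliage, fruit; D in cm, H in m, masses in kg). The component
coefficients and the carbon fraction 0.5034 are taken as fixed constants of
the target species and region; refitting them from destructive samples is
out of scope. Plot AGB converts to Mg ha⁻¹ with the exact surveyed plot
area when available (10/area(m²) combines kg→Mg and m²→ha). Trees below the
5 cm calliper limit are excluded from every plot summary, matching the
measurement protocol the allometry assumes. D and H units (cm/m) and the kg
output unit are the conventional ones for this allometry family; they are
assumptions, the equations are printed unitless in their sources.

## Synthetic stands and LiDAR

The generator's defaults define the study conditions: 94 plots of
20 m × 20 m, ~61 stems/plot (matching a 5734-tree campaign), truncated
Weibull(2.3, 18 cm) DBH, height curve H = 1.3 + 1.1·D^0.85·exp(ε) with
ε ~ N(0, 0.15²), and a merged pulse density of 3.43 m⁻².

Two stand-structure features are deliberate. First, a per-plot lognormal
site effect (sd 0.15) on the DBH scale creates between-plot variation in
stand development, so mean heights carry real information about carbon.
Second, a sparse veteran overstory (Poisson mean 3 trees/plot,
DBH ~ Weibull(6, 50 cm)) emulates the scattered old trees of an unmanaged
reserve stand. Veterans matter statistically: Lorey's height weights trees
by basal area, so a handful of veterans dominates LorH while adding
comparatively little to plot totals — this is what makes LorH a markedly
weaker carbon predictor than the arithmetic mean height, as observed in
such stands. Without them, AvgH and LorH are statistically
interchangeable and the documented predictor ordering (BA ≫ TCH > AvgH >
LorH) is not reproduced.

Crowns are cones (apex at the tree top, base radius 0.07 m per cm DBH at
the crown base, live crown 60% of height); an ellipsoid alternative sits
behind `crown_shape`. The scanner places pulses on a jittered square grid
(flight-line geometry is not simulated; only the merged multi-pass density
matters downstream), intersects each pulse with every crown footprint it
falls in, keeps the highest surface (first-surface occlusion, no
radiometric intensity), adds Gaussian ranging noise (sd 0.05 m), emits a
penetrating ground echo with probability 0.45, and labels a small fraction
(0.002) of pulses as gross z-outliers (±25–80 m) to exercise noise
filtering. Terrain is a smooth low-relief sinusoid (amplitude 2 m over
~150 m wavelengths) around 2800 m elevation.

What the simulator does **not** emulate: within-crown multiple scattering
and partial hits, scan-angle and footprint effects, understorey vegetation,
species mixtures, GPS/IMU georeferencing error, and terrain breaklines.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the estimation chain under a clean, known forest — not sensor
realism.

## LiDAR processing choices

* **Noise filter**: points further than 20 m from their 10 m-cell median
  elevation are labelled noise (gross outliers only).
* **Ground classification**: grid-minimum rule — points within 0.3 m of
  their 2 m-cell minimum are ground. Adequate for low-relief terrain; on
  steep slopes a progressive densification filter would be needed.
* **DEM**: 2 m cell mean of ground elevations, empty cells filled by IDW
  (power 2, 12 neighbours); heights above ground by bilinear interpolation,
  vegetation heights clamped at ≥ 0.
* **CHM**: rasterized from the normalized cloud — one point: its height;
  several: their mean; ground-only cells: 0; empty cells: IDW (power 2,
  k = 12, no radius cap). The raster origin snaps to a pixel-size multiple
  so a 20 m plot tiles into whole pixels (400 at 1 m).
* **TCH**: arithmetic mean of the non-nodata CHM cells whose centres fall
  inside the plot polygon.
* **Percentile metrics**: height percentiles by linear interpolation
  between order statistics over returns above a 2 m cutoff (all returns by
  default, first-returns-only switchable). Density metrics dXX = fraction
  of all returns above XX% of the plot's maximum normalized height — a
  declared definition, chosen so dXX ∈ (0,1] and ln dXX is well defined;
  vendor tools differ and no single canonical formula exists. CC =
  fraction of first returns above 2 m.

## Model fitting

All power-form models are fitted by OLS after natural-log transformation;
R² is reported on the log scale where the fit happens (a back-transformed
R² is also exposed on the fit object). RMSE is computed on back-transformed
predictions in original units, with no retransformation bias correction by
default; Baskerville's exp(σ²/2) smearing factor is available via
`bias_correction=True`. Cross-validation uses seeded shuffled k-fold
(default k = 10; k = n gives the jackknife) with R² pooled over out-of-fold
predictions.

The percentile regression starts from the full log-log model in all eleven
candidate metrics and removes the largest-p coefficient until all retained
p-values clear the removal threshold. The threshold is Bonferroni-corrected,
α/M with α = 0.05 over the M candidates, not a plain per-test α: backward
elimination keeps the *smallest* p-values to the end, so with ~10 irrelevant
candidates a plain α = 0.05 rule falsely retains at least one metric in
roughly 40–55% of fits (we verified this by simulation), whereas the
corrected rule holds family-wise false retention near α. Exactly duplicated
predictor columns are dropped with a warning before selection; a singular
design in the retained set raises rather than silently pseudo-inverting.

Degenerate cases are defined, not accidental: a constant predictor yields
slope 0, a = geometric mean, R² = 0; non-positive values anywhere in a log
domain raise with the offending indices; the daisy chain refuses to predict
where the linear BA′ link goes non-positive.

## Mapping and sensitivity

The fishnet tiles the scanned extent with axis-aligned square cells
(default 20 m, matching plot size and orientation); partial edge cells are
clipped, kept, flagged, and enter totals with their true area. Grid metrics
are extracted exactly as for calibration plots, so when the fishnet
coincides with the plots, per-cell TCH is bit-identical to per-plot TCH.
Cells without usable returns, or with metrics outside a model's positive
log domain, become nodata and drop out of summary denominators. Total
stock is Σ ACD·area(ha); density-class percentages default to map
quintiles with configurable breaks. The pixel-size experiment rebuilds the
CHM at each size (default 1–10 m), re-extracts TCH, refits the power model
and tabulates R²/RMSE; a pixel larger than the plot side is rejected.

## Reproducibility

One run seed is fanned out to per-stage substreams via spawned seed
sequences, so stages are independently reproducible and a rerun of
`run_pipeline` with the same configuration is byte-identical (JSON reports
are written with sorted keys and floats rounded at the 10th decimal).
Problem sizes used by the shipped replica study: 94 plots (~6000 trees,
~176k returns over ~3.8 ha), 10-fold cross-validation, 1–10 m sensitivity
ladder. The statistical property tests use 50–200 Monte-Carlo replicates
per claim, sized so that binomial sampling noise stays well inside the
asserted margins.

## Known limitations

* The ground classifier and DEM are tuned for gentle terrain; steep or
  discontinuous terrain would degrade ground recall before anything else.
* The simulator's canopy is opaque to first surfaces only; real penetration
  profiles produce richer vertical return distributions, so absolute values
  of density metrics are not comparable to real campaigns.
* Back-transformed RMSE without bias correction slightly underpredicts the
  mean on strongly heteroscedastic data; enable smearing when absolute
  totals matter.
* Map totals assume a planar local coordinate system; no CRS reprojection
  is performed.
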