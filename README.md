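# canopyfuse

Quadrat-scale prediction of forage (alfalfa/lucerne) above-ground dry
biomass from fused UAV multispectral imagery and airborne LiDAR point
clouds, using a weighted heterogeneous tree ensemble.

Destructive clip-and-dry sampling gives accurate biomass but cannot
scale; single-sensor remote estimates lose accuracy where dense
canopies saturate spectral indices. `canopyfuse` implements the full
chain from co-registered rasters and point clouds to per-quadrat
predictions, for agronomists and remote-sensing researchers who work
with 1 m × 1 m calibration quadrats:

1. **Registration** — bivariate polynomial transform (order 1–3) fitted
   by least squares on control-point pairs, with RMSE-driven order
   selection and iterative rejection of the worst pair.
2. **Spectral features** — per-ROI masking cascade (NDVI < 0.20 non-
   vegetation, NIR < 0.05 shadow, any band > 0.95 saturation, strict
   1st/99th-percentile trim), then band statistics and percentiles,
   histogram-shape features, and the mean of six vegetation indices:

   NDVI = (NIR−Red)/(NIR+Red), NDRE = (NIR−RE)/(NIR+RE),
   GNDVI = (NIR−G)/(NIR+G), MSR = (NIR/Red−1)/(NIR/Red+1),
   EVI = 2.5(NIR−Red)/(NIR+6Red−7.5Blue+1),
   SAVI = (1+L)(NIR−Red)/(NIR+Red+L).

3. **Structural features** — statistical outlier removal, progressive
   morphological ground filtering, height-above-ground normalization
   (vegetation window 0.05–3.0 m), then canopy height statistics and
   percentiles (Hq05…Hq95, HIQR, Hcv), point densities, coverage above
   0.3/1.0 m, vertical stratification proportions, echo-intensity
   statistics, and convex hull area.
4. **Selection** — random-forest impurity importance. For node *t*,
   I(t) = (1/N_t) Σ (y_i − ȳ_t)²; a split on feature *j* contributes
   ΔI(t,j) = I(t) − (N_L/N_t)I(t_L) − (N_R/N_t)I(t_R); per-tree sums are
   averaged over the forest, normalized, and the shortest prefix with
   95% cumulative importance is kept.
5. **Ensemble** — robust scaling (median/IQR), then random forest,
   extra trees and histogram gradient boosting combined by weighted
   soft voting, ŷ = w_RF ŷ_RF + w_ET ŷ_ET + w_HGB ŷ_HGB, with the
   simplex weights chosen to maximize 10-fold out-of-fold R² on the
   training set.
6. **Evaluation** — R², RMSE, MAE; residual moments and Q-Q
   coordinates; residuals stratified by biomass quartile and by fixed
   intervals (<1.0, 1.0–1.3, 1.3–1.6, >1.6 kg m⁻²); per-growth-stage
   metrics; feature-combination (spectral-only / LiDAR-only / fused)
   and top-k ablation studies.

Because field campaigns of this kind are rarely public, the package
ships a first-class synthetic scene generator
(`canopyfuse.synthetic_scene`) producing co-registered rasters, point
clouds and quadrats with known generative biomass, including spectral
saturation at high biomass, canopy-penetration ground returns, and
shadow/saturation/outlier contamination. See `docs/methods.md` for the
generative model and its limits.

## Worked example

```yaml
# run.yaml
band_order: [Blue, Green, Red, RedEdge, NIR]
seed: 42
output_dir: runs/demo
scene:
  n_quadrats: 120
  cloud_shift: [0.25, -0.15]   # rigid cloud offset recovered by registration
model:
  hyperparameters:
    RF: {n_estimators: 300}
    ET: {n_estimators: 400}
    HGB: {max_iter: 400}
```

```bash
$ canopyfuse all --config run.yaml
run complete: R2=0.842 RMSE=0.118 MAE=0.098 -> runs/demo
```

The run directory then holds the per-stage artifacts: the generated
scene (`scene_00/`), the fitted registration transform (order 1, RMSE
≈ 0 m for a rigid shift), `mask_reports.json` (per-ROI counts of
non-vegetation/shadow/saturated/trimmed pixels), the fused
`feature_table.csv` (188 features: 85 band statistics, 6 index means,
27 structural, 66 structure × spectrum interactions, geometry and
treatment covariates), `importance_ranking.csv`, the selected 95%
subset, the saved ensemble (`model/manifest.json` records weights
(w_RF, w_ET, w_HGB) = (0.00, 0.95, 0.05) and out-of-fold R² 0.914 for
this run), and `evaluation_report.json`. The headline numbers mean: on
the 18 held-out quadrats the ensemble explains 84% of biomass variance
with a typical error of ~0.12 kg m⁻² against a mean biomass of
~1.27 kg m⁻².

The same stages are available from Python (`canopyfuse.run_pipeline`)
or individually (`generate_scene`, `extract_spectral_features`,
`structural_features`, `impurity_importance`, `fit_ensemble`, …).

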