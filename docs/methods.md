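# Methods

This note documents the models, conventions and design choices behind
`canopyfuse`, in the spirit of a model-description appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## 1. The estimation problem

Each sample is a 1 m × 1 m quadrat whose oven-dry above-ground biomass
(kg m⁻²) is the regression target. Two co-registered data sources
describe the quadrat: a 5-band reflectance raster (Blue, Green, Red,
RedEdge, NIR) and a LiDAR point cloud with echo intensity. The method
assumes (i) both sources are radiometrically/geometrically
preprocessed upstream (orthomosaics, trajectory-corrected clouds);
(ii) residual misalignment between them is a smooth planar distortion
correctable by a low-order polynomial on manually picked control
points; (iii) biomass information enters through canopy *greenness*
(spectral response) and canopy *structure* (height distribution,
closure), each an imperfect proxy.

## 2. Synthetic scene generator

The generator emulates one UAV flight batch over a fertilizer-gradient
trial. Its defaults are the package's study conditions; all sampling
flows through a single `numpy` generator seeded from the config, so a
(config, seed) pair is byte-reproducible.

Per quadrat *i*:

* dry biomass `b_i` ~ truncated normal(mean 1.27, sd 0.41) on
  [0.3, 2.2] kg m⁻² (a `uniform` option spans the range evenly for
  rank-correlation checks), shifted by 0.12·(fertilizer level − mean
  level), with the six field levels {0, 0.5, 0.75, 1.0, 1.25, 1.5}
  assigned cyclically;
* two latent drives decouple the modalities from biomass:
  `b_spec = b·exp(ε_s)`, `b_struct = b·exp(ε_h)` with independent
  ε_s ~ N(0, 0.10), ε_h ~ N(0, 0.20). This is the generator's model of
  biological scatter — equal dry weights with different architecture,
  water status and greenness. Structure gets the larger scatter
  because height is the more indirect proxy of dry matter;
* canopy cover `c = 1 − exp(−k·b_spec)` with k = −ln(0.05)/2, so cover
  saturates near 0.95 at 2 kg m⁻² — the source of the high-biomass
  spectral saturation and of the underestimation diagnosed downstream;
* height scale `h = h_max·b_struct/(b_struct + b_half)` with
  h_max = 1.2 m, b_half = 0.7 kg m⁻²: a saturating Michaelis–Menten
  form with realistic lucerne canopy heights (mean point height
  0.4·h ≈ 0.15–0.45 m).

Pixels inside a quadrat take the linear soil↔canopy mixture
`soil + (veg − soil)·c` per band (soil NDVI ≈ 0.09, dense-canopy
NDVI ≈ 0.90) plus N(0, 0.015) noise; background pixels are bare soil.
Shadow contamination (3% of quadrat pixels) scales all bands so
NIR < 0.05 (ratio indices unchanged — caught by the NIR stage, as in
real shadow); sensor saturation (1%) forces NIR to 0.97.

LiDAR returns arrive at 175 pts m⁻² (a mid-range mapping density).
Within a quadrat a pulse is a canopy return with probability
`0.85·c(b_struct)` — the 0.85 is canopy penetration, keeping ground
returns available under closed canopies as multi-return systems do.
Canopy heights follow Beta(2, 3)·h clipped to [0.05, 3.0] m (right-
skewed profile), plus N(0, 0.02 m) ranging noise; ground returns sit
on a 2% planar slope with 1 cm noise; intensity is N(120 + 80c, 15)
for canopy and N(60, 10) for ground; each quadrat receives 2 high
outliers at 4–9 m. The cloud can be rigidly shifted against the
raster, with seven emitted control-point pairs tying it back.

**What the generator does not emulate:** radiative transfer, BRDF and
view-angle effects, mixed pixels at quadrat edges, multi-return
waveforms, terrain roughness, weeds/lodging, registration distortions
beyond global polynomials, and spatial autocorrelation between
quadrats. Passing tests therefore demonstrate that the pipeline
recovers the constructs this model encodes — monotone saturating
responses with two partially decoupled modalities — not field-ready
accuracy on real canopies.

## 3. Numerical conventions

* **Percentiles** — linear interpolation between order statistics
  everywhere (band statistics, height percentiles, quantile masks).
* **Standard deviations** — sample (ddof = 1) for features; residual
  skewness and excess kurtosis are the bias-uncorrected moment forms
  (normal ⇒ 0/0).
* **Histogram features** — 50 equal-width bins over the sample
  min–max; modal ties break to the lower-valued bin; distribution
  width counts bins with ≥ half the modal count times the bin width.
  A degenerate (constant) sample is a point mass: frequency 1, width 0.
* **Pixel membership** — pixel *centers* tested against the strict
  interior of the inward-buffered polygon (default buffer 0.075 m, the
  midpoint of the 5–10 cm range used for edge-effect suppression).
* **Masking cascade order** — non-vegetation (NDVI < 0.20, computed
  from raw Red/NIR), shadow (NIR < 0.05), saturation (any band
  > 0.95), then per-band strict 1st/99th-percentile trimming on the
  survivors, with cross-band features computed on the intersection of
  per-band survivors. The three threshold stages are pointwise and
  idempotent. The percentile trim is rank-based, so a second pass over
  its own survivors would trim again (for any sample of >101 distinct
  values the 1st percentile lies strictly inside the data); the
  cascade therefore runs exactly once per ROI, and its counts are
  reported per stage in cascade order.
* **HAG window** — closed bounds [0.05, 3.0] m with a 1e-9 tolerance
  so boundary points survive float round-off.
* **Vertical strata** — half-open [0, 0.5), [0.5, 1.0), [1.0, 1.5) m
  with a closed top bin [1.5, 3.0] m, so proportions sum to exactly 1.
  Coverage thresholds are strict (H > 0.3, H > 1.0).
* **Ground filter** — grid-minimum surface (0.25 m cells, empty cells
  filled from the nearest occupied cell), opened with windows of
  3, 5, 9, … cells up to 2 m; a cell is carved down to the opened
  surface when it exceeds it by 0.10 m + 0.15·(half window extent),
  capped at 2 m; points within 0.10 m of the final surface are ground.
  The height-normalization surface is the bilinear interpolation of
  the grid minimum of classified ground points.
* **Outlier filter** — mean distance to the 8 nearest neighbours,
  thresholded at global mean + 3 sample standard deviations.
* **Registration basis** — monomials ordered by total degree, then by
  descending x-power (order 2: 1, x, y, x², xy, y²); order selection
  prefers the lowest order meeting the RMSE threshold (default: one
  reference pixel), dropping at most ⌊n/5⌋ worst pairs; with 7 pairs an
  order-3 model (10 coefficients) is refused as underdetermined.
* **Split rule** — train size ⌊0.85·n⌋ (270 → 229/41); seeded uniform
  permutation, no stratification.
* **Seeds** — every stochastic component derives its seed from the
  root seed via `numpy.random.SeedSequence([root, salt])` with fixed
  salts, keeping all derived seeds below 2³¹.

## 4. Importance and selection

Impurity importance follows the variance-reduction form: per split,
ΔI(t,j) = I(t) − (N_L/N_t)I(t_L) − (N_R/N_t)I(t_R), summed over the
nodes of each tree that split on *j*, averaged over trees, and
normalized to sum to 1. Note the per-node reductions are **not**
additionally weighted by the node fraction N_t/N; scikit-learn's
`feature_importances_` applies that extra weight and is therefore used
only as a qualitative cross-check in tests, while the package computes
its importances directly from the fitted trees' node arrays and
exposes per-node ΔI for verification. Selection keeps the shortest
descending-importance prefix reaching 95% cumulative importance, with
ties broken lexicographically for determinism. Importance is computed
on the training split only.

Interaction features are plain products (height percentile × index
mean and stratum proportion × index mean, named `a_X_b`): a product is
the minimal construction that vanishes when either factor does, which
is what "joint" features are meant to express; ratios were rejected as
unbounded under near-zero denominators.

Quadrats with fewer than 5 vegetation returns get their structural
features imputed with the across-quadrat median and a
`structural_absent` indicator column, keeping rows usable while
letting the model see the absence.

## 5. Ensemble

Features are robust-scaled (median centering, IQR scaling, unit scale
where the IQR collapses) on the training set. Base learners and their
default hyperparameters: random forest (1000 trees, depth 15,
min-split 5, min-leaf 2, sqrt features), extra trees (1200 trees,
unlimited depth, min-split 4, min-leaf 1, no bootstrap, sqrt
features), histogram gradient boosting (1000 rounds, learning rate
0.05, depth 8, min-leaf 5, L2 = 1). Soft-voting weights are chosen on
10-fold out-of-fold training predictions over the simplex lattice of
step 0.05 *plus* the exact equal-weights point, maximizing out-of-fold
R²; ties break toward equal weights, then lexicographically. Because
the lattice contains the simplex vertices, the chosen combination
never scores below the best single learner out of fold. The test set
enters only at final evaluation. An exhaustive grid-search helper
(deterministic fold assignment, full results table) is provided but
off by default.

## 6. Reference benchmark and problem sizes

The packaged benchmark (`canopyfuse.benchmark`) generates one
300-quadrat scene at the defaults above with a (0.25, −0.15) m rigid
cloud shift, runs the full pipeline, and adds the feature-combination
study. It uses a desk-scale tree budget — RF 300, ET 400, HGB 400
rounds, everything else at the defaults — since on a few hundred
training rows the larger default forests change test metrics only
marginally at several times the cost. Unit tests use still smaller
forests (40 trees) where only behavioural contracts, not accuracy, are
asserted.

## 7. Residual conventions and diagnostics

Residuals are observed − predicted, so *underestimation is positive*.
Absolute-residual bins use cuts {0.1, 0.2, 0.3} kg m⁻² (lower-closed);
biomass intervals are <1.0, [1.0, 1.3), [1.3, 1.6), ≥1.6 kg m⁻²;
quartile groups are lower-closed with closed extremes and partition
the test set. Per-stage metrics flag subsets under 5 samples (or with
constant targets) as low-confidence with absent R².

## 8. Known limitations

* The GeoTIFF sidecar carries only an axis-aligned north-up
  geotransform; no CRS handling or rotation.
* The ground filter assumes gently sloped terrain; steep or terraced
  sites would need slope-adaptive thresholds.
* The percentile trim is order-dependent by design (documented above);
  feature values depend on the cascade being run exactly once.
* The unweighted per-node importance inflates the contribution of deep
  small-node splits relative to node-weighted variants; with feature
  subsampling (`sqrt`) on many features this diffuses importance and
  the 95% prefix is correspondingly long. Rankings, not absolute
  values, are the intended use.
* No spatial cross-validation: quadrats are treated as exchangeable,
  which synthetic scenes satisfy by construction but field plots may
  not.
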