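# Methods

This note documents the models, defaults and design choices behind
`sdmniche`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A `RasterGrid` is a north-up single-band grid: a value array, a
top-left-origin affine transform with square cells, a boolean nodata
mask, and a `crs_kind` of either projected metres or geographic degrees.
Cells are half-open with their left and top edges inclusive; row 0 is
the northern edge. A `PredictorStack` is a set of mutually aligned
grids carrying the union of member masks. Rasters serialise as ESRI
ASCII grids — a plain-text format every GIS reads — with the CRS kind
recorded in a header comment.

Geographic distance is the haversine on a sphere of radius
6,371.0088 km (the IUGG mean radius); projected inputs use Euclidean
distance. Geographic cell areas use the per-row cosine rule
(side = cell°·πR/180, area scaled by cos latitude), and Horn-slope cell
spacing converts degrees to metres at each row's latitude with the same
spherical model. These spherical approximations are accurate to ~0.3 %,
far below the other uncertainties in this kind of analysis.

## Synthetic landscapes and virtual species

`generate_env_stack` produces per-predictor fields by smoothing white
noise with a gaussian kernel (default σ = 8 cells, giving realistic
spatial autocorrelation), **empirically whitening** the stacked fields,
and mixing them through the symmetric square root of the target
correlation matrix before an affine rescale to each predictor's value
range. The whitening step matters: smoothing leaves few effective
degrees of freedom per field, so without it the realised
cross-correlation of "independent" fields can drift by ±0.4; with it
the imposed correlations hold essentially exactly over the generated
cells. The default scenario is a 200×200 grid of 1-km projected cells
with five predictors (bio5 18–48 °C, bio6 −12–8 °C, bio12 50–1,200 mm,
bio18 0–300 mm, elevation 0–3,500 m), uncorrelated unless requested.

A `VirtualSpecies` combines per-predictor gaussian (optimum, width) or
logistic (midpoint, rate) responses by product (or geometric mean), so
combined suitability is in [0, 1] and equals 1 where every predictor
sits at its optimum. Presences are drawn with cell probability
proportional to suitability ("probabilistic" virtual-species design,
preserving the gradient that response-curve recovery needs) and
jittered uniformly within the cell; background cells are drawn
uniformly without replacement from valid cells.

What the generator does *not* emulate: anisotropic terrain, realistic
valley/ridge structure, sampling bias (roadside effects), detection
error, and temporal non-stationarity. Passing tests therefore
demonstrate that the pipeline's estimators are correct and convergent,
not that any particular field dataset meets their assumptions.

## Occurrence cleaning

De-duplication keeps the first record per grid cell (deterministic).
Thinning enforces a minimum pairwise distance (default 5 km) by
randomized greedy removal: repeatedly delete the point with the most
remaining conflicts, ties broken by a seeded RNG, restarted
`n_repeats` (default 100) times keeping the largest surviving set. On
fixtures small enough to enumerate, this matches the exhaustive
maximum-retention optimum (asserted in the tests); in general it is the
standard practical approximation. Thinning an already-thinned set is a
no-op.

## Predictor engineering

Slope uses Horn's 8-neighbour weighted finite differences in degrees;
border cells and cells adjacent to nodata are masked rather than
estimated from fewer neighbours. Topographic heterogeneity is the
sample standard deviation (denominator n − 1) of fine-scale elevation
within coarse blocks (e.g. 90-m cells inside 1-km blocks); partial edge
blocks are computed when at least two fine cells are valid. Stepwise
VIF regresses each predictor on all others with an OLS intercept,
drops the max-VIF predictor while any VIF ≥ threshold (default 10, the
conventional cutoff), and reports the removal order; exactly collinear
pairs lose their later-listed member first.

## The five algorithms

All are presence (1) vs background (0) fits on internally standardised
predictors (training mean/SD over presences + background), exposing one
contract: predictions in [0, 1], deterministic after fitting, constant
predictors dropped with a warning.

* **GLM** — unpenalised logistic regression with linear + quadratic
  terms per predictor; the quadratic terms are what allow unimodal
  (niche-shaped) response curves. On non-convergence the fit falls back
  to a small ridge penalty (C = 100), logged.
* **GAM** — logistic fit on cubic B-spline bases with one interior knot
  at the training median: 5 basis functions per predictor, one dropped
  for identifiability, i.e. 4 effective df. A mild ridge (C = 1000)
  stabilises the basis collinearity.
* **GBM** — `GradientBoostingClassifier` with 2,000 trees, learning
  rate 0.01, depth 3, bag fraction 0.5 (classic slow-learning SDM
  settings), seeded.
* **Maxent** — written from scratch: a Gibbs density
  q(x) ∝ exp(λ·f(x)) normalised over the background sample, maximising
  the presence log-likelihood with an L1 penalty
  α = m·√(log n_presence / n_presence) (regularisation multiplier
  m = 1 by default), optimised by L-BFGS-B on the positive/negative
  part split of λ. Features: linear + quadratic always; pairwise
  products and 5-knot forward/reverse hinges per predictor once
  n_presence ≥ 80 (mirroring standard Maxent feature ramps). The fitted
  density sums to 1 over the background by construction (asserted to
  1e-6 in tests). Map output uses the complementary log-log transform
  anchored at the entropy H of the background density,
  1 − exp(−e^H q(x)), so a cell of uniform density scores ≈ 0.632.
* **RF** — 500 trees with `class_weight="balanced_subsample"`
  (per-tree class re-balancing), seeded. A balanced-bootstrap variant
  (equal-size resamples per class) was evaluated and not adopted: it
  smoothed the probability maps but did not improve ensemble-level
  recovery.

Background size defaults to 10,000 cells (or all valid cells if fewer).

## Evaluation

* **AUC** is computed in its Mann–Whitney form (ties ½) and is
  invariant under monotone transforms of the scores.
* **Threshold metrics** scan all observed score values; sensitivity is
  the presence fraction ≥ threshold, specificity the background
  fraction < threshold (background points stand in for absences — no
  true absences exist in this design), TSS their sum minus 1; ties
  resolve to the lowest threshold.
* **Continuous Boyce index**: 101 windows of width 10 % of the
  landscape-score range; per window P (presence fraction in window) /
  E (landscape fraction); the index is the Spearman correlation of P/E
  with the window midpoint over windows with E > 0. Degenerate inputs
  (constant scores, < 3 usable windows, constant P/E) return 0 with a
  warning.
* **Boyce and small held-out sets.** With an 80/20 split of 200
  records, the 40 held-out presences cannot populate the narrow
  high-suitability windows (whose E covers a handful of cells), and the
  held-out Boyce collapses even for near-perfect surfaces while the
  all-presence value sits near +1 — a small-sample artifact of the
  windowed construction. Since Boyce is a calibration metric rather
  than a discrimination metric, the pipeline's headline Boyce is
  computed over **all** presences (standard practice), while AUC and
  TSS remain strictly held-out; both Boyce variants are reported in the
  pipeline's metrics files (`boyce` = held-out, `boyce_all_presences`).
* **Ensemble** maps are cellwise weighted means — uniform by default,
  optionally weighted by member TSS clipped at zero. **Permutation
  importance** is 1 − Pearson correlation between predictions on the
  intact table and on the table with one column permuted, averaged over
  repeats (default 10) and clipped to [0, 1]. **Suitable area** counts
  cells ≥ threshold (default: the ensemble's max-TSS threshold,
  recorded in metadata), each weighted by its km² area.

## Niche overlap

Overlap is computed on continuous (normally ensemble) suitability, not
on binary maps: cells that are nodata in either surface are excluded
from both, each surface is normalised to sum to 1 over the shared
support, and D = 1 − ½ Σ|p_i − q_i| (Schoener) and
I = 1 − ½ Σ(√p_i − √q_i)² (Hellinger) are reported. Both are symmetric,
bounded in [0, 1], and equal 1 iff the normalised surfaces coincide.

## Validation experiments and problem sizes

The acceptance experiments run on the default 200×200 scenario with
uncorrelated predictors:

* **Niche recovery** — one species with gaussian responses on bio12
  (optimum 600 mm, σ = 100 mm) and bio5 (optimum 45 °C, σ = 3 °C),
  200 presences, 10,000 background. Checks: GLM response-curve peak
  within 600 ± 50 mm; ensemble held-out AUC ≥ 0.85; all-presence Boyce
  ≥ 0.7; permutation importance ranks the informative predictors above
  all noise predictors. The two-axis niche makes the species strongly
  separable (niche width ≪ predictor range); a single wide
  precipitation response is not identifiable to that AUC on a landscape
  whose modal precipitation lies near the optimum.
* **Overlap recovery** — two species with *identical* niches,
  independently sampled (500 presences each) and modelled end-to-end,
  must give ensemble D ≥ 0.9; a species whose optima sit ≥ 3σ away must
  give D ≤ 0.4; D on true surfaces decreases strictly along a ladder of
  niche offsets. The identical-pair D converges with presence count
  (≈ 0.87–0.89 at 150–200 presences, where presence-sampling noise in
  the overfit-prone tree members still dominates; ≈ 0.9+ at 500), so
  this experiment runs at 500 presences, where estimation rather than
  sampling error is the limiting factor.
* **Pipeline determinism** — the packaged `two-prey-demo` (120×120 km,
  four predictors, species of 45/200/110 raw records echoing
  field-study sample sizes) rerun with the same config and seed must
  reproduce every CSV/JSON/ASC output bit-for-bit; one global seed
  derives per-stage seeds by stage-name hashing.

Problem sizes were chosen so the full suite runs in minutes on a single
CPU while leaving the estimators in their convergent regime.

## Known limitations

* Maxent hinge knots are fixed at 5 quantile positions per direction;
  classic Maxent uses many more, trading smoothness for fit.
* The GAM uses a fixed-df basis rather than penalised smoothness
  selection; responses wigglier than 4 df allows will be under-fit.
* Thinning is O(n²) in memory/time (pairwise distances); fine for
  record sets in the thousands, not for millions.
* The single 80/20 random split follows common practice but understates
  spatial autocorrelation between train and test; no spatial
  cross-validation is provided.
* Area and distance computations assume a sphere; no projected CRS
  transformations are performed (inputs must already share a grid or be
  resampled by `align_stack`, which is nearest-neighbour only).
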