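# Methods

## Problem setting

The package estimates where a wide-ranging terrestrial species could occur
and move across a landscape split into three horizontal strata: a forested
massif in the north, an intensively cultivated plain in the centre, and
vineyard-and-woodland hills in the south. Occurrence data come from two
study sub-areas — one in the plain (rice paddies occur only there) and one
in the hills (vineyards only there) — and the analysis must extrapolate the
fitted habitat models to the whole landscape, including the uninvestigated
massif. Connectivity is then asked of the resulting suitability surface:
does a corridor of low movement resistance cross the hostile plain?

## Synthetic landscape and virtual species

Real land-cover cartography and field occurrences are replaced by a
generator whose defaults encode the study conditions end to end, so every
downstream stage is testable without external data.

**Land cover.** Nine classes (urban, arable, rice paddies, vineyards,
complex cultivations, meadows, transitional woodland, woodland, water).
Per stratum, a target mix is realised by a per-class race: each class gets
an independent Gaussian random field smoothed with an isotropic kernel of
scale `patch_scale_cells` (default 3), rank-transformed to Uniform(0,1);
the cell takes the class minimising `−log(u)/f` where `f` is its target
fraction. Because `−log(u)/f ~ Exponential(f)`, each cell's marginal class
probability equals its target exactly, while smoothing produces coherent
patches. Exclusive classes are simply excluded from the race outside their
sub-area rectangle, which confines them deterministically (their realised
share is then concentrated inside the rectangle). Rivers are carved last as
1-cell-wide random-walk polylines of water crossing the plain stratum; the
first river is routed through the plain sub-area so a riparian strip always
crosses it. Default raster: 64 × 64 cells at 100 m — a deliberately
scaled-down landscape (≈ 41 km², versus the ~11,000 km² of the motivating
study region) chosen so the full analysis runs in seconds; all structural
relations (strata, sub-areas, exclusive covers, river corridor) are
preserved at this scale.

**Virtual species.** True occurrence probability is
`logistic(β₀ + Σ β_c · cover_c)` on 100-m buffer fractional covers, with
defaults reflecting forest-carnivore habitat selection: woodland +4,
water +4, transitional woodland +1.5, meadows 0, complex cultivations −0.5,
vineyards −1, arable −2, urban −3, rice paddies −3, β₀ = −1.5. Presences
(defaults 96 in the plain sub-area, 71 in the hills, matching the survey
the design emulates) are drawn without replacement with probability
proportional to this suitability and placed at cell centers, so their
covariates are exactly recomputable. Pseudo-absences (defaults 300 and 500,
proportional to sub-area size) are uniform over the sub-area and are *not*
excluded from presence cells. A second sampler
(`sample_bernoulli_occurrences`) draws cells uniformly and labels each by a
Bernoulli draw at the true probability; only under that design is the full
coefficient vector of the generating model identified, so it is the basis
of parameter-recovery checks. What the generator does **not** emulate:
spatial sampling bias along transects, observer error, temporal structure,
real hydrology/roads, and polygon (vector) land cover — passing tests
therefore demonstrate the correctness of the computational chain, not field
realism.

## Covariates

`fractional_cover` counts raster cells whose *centers* fall within the
buffer radius (default 100 m) of a point — a declared convention chosen for
exact reproducibility over area-weighted polygon intersection; the two
converge as cells shrink. Landscape-wide projection uses a disc-kernel
convolution that is provably identical to the per-point rule (both routes
are ratios of the same integer counts). The collinearity screen reports all
pairwise sample Pearson correlations (denominator n−1) and flags |r| >
0.60; it deliberately reports rather than drops — variable removal is a
configuration action. Zero-variance columns (a class absent from a
sub-area) are excluded from the screen and dropped before fitting.

## Distribution models

* **GLM** — binomial logit with linear terms, fitted by penalised maximum
  likelihood with a small ridge (`1e-4` per-sample; intercept unpenalised).
  The ridge is negligible on informative data but keeps coefficients finite
  under complete separation. Standard errors come from the inverse Fisher
  information at the fit.
* **GBM** — stagewise gradient boosting on logistic deviance; defaults 500
  stages, learning rate 0.05, depth 3, bag fraction 1 (declared defaults:
  no canonical values exist for them in this design). Training deviance is
  non-increasing by construction and exposed for verification.
* **MaxEnt** — a Gibbs distribution over the background sample (the
  pseudo-absence rows) with linear + quadratic features standardised
  against the background. Fitting maximises the L1-penalised presence
  log-likelihood via a smooth split-variable L-BFGS-B; at zero penalty the
  optimum satisfies the moment-matching property (Gibbs feature expectation
  = empirical presence mean), which the tests verify against a direct
  numerical optimiser. The penalty defaults to the value (grid 0.005–0.2)
  maximising held-out log-likelihood on a 20% presence holdout. Predictions
  use the standard logistic output `expit(H + log q̂(x))`, with `H` the
  entropy of the fitted Gibbs distribution. Hinge/threshold features are
  not implemented.

**Evaluation.** Three replicated stratified 75/25 splits (identical splits
across model kinds); AUC in the Mann–Whitney form with ties counted ½; TSS
maximised over all threshold midpoints. Ensemble predictions are the
weighted mean of member predictions with weights ∝ mean test AUC (no
exponent, no quality floor — weighting only). Variable importance is the
randomisation measure: 1 − |Pearson r| between predictions on the intact
table and on the table with one column permuted, averaged over 10
permutations.

## Suitability maps

Each area ensemble is projected to every cell from its buffer covariates on
a 0–1000 scale. Before integration, cells of a land-cover class never seen
by an area's model (the other area's exclusive cover) are set to 0 in that
map. The two maps are merged by per-pixel maximum — keeping the less
conservative estimate where the models disagree — and normalised to 0–1 by
dividing by the fixed 1000 ceiling. Min–max normalisation was rejected: it
would let the observed maximum redefine the scale and break comparability
between maps. `suitable_fraction` uses a strict `> 0.5` rule.

## Resistance and connectivity

`R(h) = r_max^(1−h)` with `r_max = 100` by default: a single-parameter
negative exponential hitting both endpoints (R = 1 at h = 1, R = r_max at
h = 0), so most of a moderately suitable landscape is cheap to traverse and
only strongly unsuitable cells are costly. Sources are centroids of 1-km
grid cells containing at least one pixel above 0.5; in the massif stratum
(never field-surveyed, sporadically occupied) qualifying centroids are
thinned to one per 5-km block, keeping the cell with the highest maximum
suitability (ties: lowest row, then column).

The cost graph connects 8-neighbour traversable cells with weight
`cell_size · (R_i + R_j)/2`, diagonals × √2; NaN cells carry no edges (no
corner-cutting checks — nodata is simply unreachable). Costs are exact
Dijkstra distances. Path reconstruction walks back from the target,
choosing among optimal predecessors the lowest linear cell index, making
outputs bit-reproducible under cost ties.

**Factorial LCP** includes every unordered source pair whose *Euclidean*
separation is within the scenario threshold (100 km low / 850 km high); a
cost-distance filter is available behind an argument but Euclidean is the
default reading. Each included pair adds 1 along one least-cost path;
unreachable pairs are skipped and reported. **Resistant kernels** use
`k(c) = exp(−d² / (2σ²))` truncated at `D = threshold_km · 1000` m with
`σ = D/3` — a declared bandwidth under which truncation discards < 1.2% of
kernel mass. Cost distance is in distance-equivalent meters (uniform R = 1
gives cost = path length). `connectivity_extent` counts cells with density
strictly above 0; whether a higher display threshold was intended in the
motivating analysis is unknowable, so 0 is the declared default.

## Pipeline, seeds, numerics

One root seed spawns independent per-stage seeds (landscape, presences,
pseudo-absences, CV splits, importance permutations) via `SeedSequence`, so
stages can be re-run in isolation and a full run reproduces its manifest
checksums exactly. Configuration is a versioned YAML schema validated by a
strict model (unknown keys rejected, ranges checked, defaults in one
place). Numerical conventions: buffer membership uses a 1e-12 distance
tolerance; path reconstruction uses a 1e-9 relative cost tolerance;
suitability range checks allow 1e-9 slack; the collinearity screen treats a
column as zero-variance only when max = min exactly.

## Known limitations

* Projection extrapolates tree-based members (GBM) beyond the covariate
  range seen in training, where they plateau; the GLM and MaxEnt members
  extrapolate smoothly. This mirrors the behaviour of the standard tools.
* The factorial LCP keeps a single optimal path per pair; corridor width is
  represented only through path coincidence across pairs, not buffering.
* At the default demo scale both dispersal thresholds exceed the landscape
  diagonal, so the two scenarios coincide; they differentiate on larger
  rasters or smaller thresholds.
* Presence-only sampling with uniform background identifies slope
  coefficients but not the intercept of the generating logistic model;
  calibration of absolute probabilities is design-dependent.
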