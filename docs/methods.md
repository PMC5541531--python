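# Methods

This note records the models and procedures `carnrange` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want to
know. Nothing here states an empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Grids, areas and distances

All rasters live on regular lon/lat lattices (`GridSpec`), 0-based, row 0
at the northern edge, cells half-open `[edge, edge + res)`. Cell areas are
spherical: for a band with edge latitudes φ₁ < φ₂ and cell width Δλ,
area = R² · Δλ · (sin φ₂ − sin φ₁) with R = 6371.0 km. A sphere rather
than an ellipsoid is used throughout: no datum is attached to the source
maps this pipeline targets, and spherical areas are exactly reproducible
and accurate to ~0.3% — well inside the uncertainty of any historic range
polygon. Distances are great circles (haversine); distance-band
neighborhoods are found with a KD-tree on 3-D sphere coordinates using
the chord length equivalent to the great-circle radius, so they match an
all-pairs scan exactly (a property the suite asserts).

The coarse model grid is produced by integer block aggregation of the
fine grid (factor = fine cells per coarse cell side). Coarse centroid
tables are exported with Lambert cylindrical equal-area coordinates
(standard parallel 0°, tagged in outputs); model-space distances use
great circles on the lon/lat centroids.

Raster I/O uses the ESRI ASCII grid format — plain text, self-describing,
readable by any GIS — with the grid's georeferencing in the header.
Polygon input is GeoJSON, rasterized by centroid containment (a cell is
burned iff its centroid is covered by a retained polygon; the IUCN-style
presence attribute, default codes {1, 2} = extant / probably extant, is
filterable).

## Harmonization rules

Order: superset enforcement → coastline adjustment (both rasters) →
land-mask intersection → altitude clip (both rasters) → final union
repair. Each step's cell deltas are recorded in the pair's provenance.

* **Superset**: historic ← historic ∪ current. Apparent expansions in the
  raw maps are treated as digitization artefacts; the report carries the
  induced % increase in historic area (area-weighted when cell areas are
  supplied).
* **Coastline**: a land cell is added when its Chebyshev grid distance is
  ≤ k (default 3 cells) to some range cell *and* ≤ k to some non-land
  cell. Chebyshev ("queen") distance matches raster-buffer intuition for
  "within three grid cells". The conjunctive reading (near range AND near
  ocean) confines the adjustment to the coastline, which is its purpose.
  The single-pass operator is not idempotent along narrow coastal strips,
  so the *pipeline* iterates it to a fixed point (capped at 100 passes);
  this makes `harmonize_species` idempotent — re-harmonizing an already
  harmonized pair is a no-op, which the suite asserts.
* **Altitude**: cells are retained iff the cell's elevation value lies in
  the species' [min, max]. The elevation raster is interpreted as a cell
  *mean* by default (the statistic is configurable); clipping applies to
  both rasters and can be disabled per species — needed for species whose
  published limits describe only the current range.

Invariants after harmonization: current ⊆ historic ⊆ land;
monotone in the inputs (enlarging the raw current range never shrinks the
harmonized historic range).

## Composite statistics

Richness composites are plain sums of binary rasters; % lost is NaN (not
0) where historic richness is zero so maps distinguish "never occupied"
from "nothing lost". A cell's guild is *intact* iff historic richness ≥ 1
and lost richness = 0. Every "% of land" figure weights cells by their
spherical area. Zonal mean richness can be weighted by area (default) or
by cell count — published regional summaries built from per-cell
histograms correspond to the count mode, so both are provided.

## The contraction model

Observations are species × coarse-cell pairs. A coarse cell belongs to a
species' historic range when the historic raster covers ≥ 50% of the
cell's fine *land* cells; the response is y = 1 when the current range
covers < 50% of those historic fine cells. Both thresholds are free
parameters (`ModelParams`); 0.5/0.5 is the natural majority rule when the
source maps state only the coarse cell size. Covariates are aggregated by
their mean over fine land cells; the region label is the land-majority
zone.

Covariates are transformed (log(1+x) for the two density covariates;
cropland, already bounded, is left untransformed — configurable) and then
z-scored with the *sample* (n−1) standard deviation; the constants are
recorded for back-transformation of effect sizes.

### Estimation

The logistic mixed model is fitted by maximum likelihood under the
Laplace approximation, implemented in-package:

* Random effects are organised as independent (factor, term) blocks with
  one relative standard deviation λ each — i.e. a *diagonal* covariance
  within a factor (lme4's `(1 + x || g)` structure). The model family
  needed here (species intercepts; region intercepts + slopes) does not
  require cross-term correlations, and the diagonal structure keeps the
  profile optimization low-dimensional and stable.
* Inner loop: Newton (penalized IRLS) on the joint (β, u) mode of
  Σ[yη − log(1+e^η)] − ‖u‖²/2 with η = Xβ + ZΛu, with step halving;
  convergence at gradient ∞-norm < 1e-8.
* Outer loop: the profiled Laplace log-likelihood
  ℓ(β̂, û) − ½‖û‖² − ½ log det(ZΛᵀWZΛ + I) is maximized over λ ≥ 0 —
  golden-section (`minimize_scalar`, xatol 1e-5) for one component,
  L-BFGS-B with numerical gradients for several.
* Standard errors come from the inverse of the joint penalized Hessian
  (β block); conditional modes b = Λû with conditional s.d. from the
  corresponding diagonal of the inverse. Wald z tests give p-values.
* With all λ pinned to 0 the fit *is* ordinary logistic IRLS (asserted to
  1e-6 against an independent GLM implementation); the full model is
  cross-checked against `lme4::glmer` (Laplace, nAGQ = 1) on one dataset.
* Non-convergence is flagged on the result, not raised; |β| > 30 triggers
  a complete-separation warning; fitted probabilities are clamped to
  [1e-12, 1−1e-12] inside deviance residuals.

### The residuals auto-covariate

Deviance residuals of the non-spatial fit are collapsed to one value per
coarse cell (mean over the species present — the default; an
observation-weighted mode is provided because the source description does
not say how multi-species cells were pooled), then averaged over all
cells within the band radius (default 300 km) of each cell. The focal
cell is excluded by default (self-inclusion is a flag). Cells with no
neighbor in the band get 0 and are counted in the run manifest. The RAC
is standardized like any covariate and appended as a fixed effect for the
refit, keeping effect sizes comparable.

**Caveat (calibration).** The RAC is built from the model's own
residuals. In a symmetric distance band every residual pair (i, j)
enters the refit's score for the RAC coefficient twice — through
rac_i ⊃ r_j and rac_j ⊃ r_i — which roughly doubles the variance of the
estimated RAC coefficient relative to the naive Wald formula. In
simulations with no spatial structure the RAC term's naive 95% CI
therefore covers zero at ~84%, not 95%, essentially independent of
lattice size (the z statistic is ≈ N(0, √2) asymptotically). Inference
*on the RAC term itself* should not be read at face value; the term's job
is to absorb spatial autocorrelation so the covariate effects are
cleaner, and the suite verifies it detects strong injected spatial fields
and leaves the remaining coefficients untouched when it is degenerate.

### Variance explained and regional effects

Pseudo-R² follows the latent-scale variance partition for logit models:
marginal = σ²_f / (σ²_f + Σσ²_r + π²/3) and conditional adds Σσ²_r to the
numerator, where σ²_f is the sample variance of the fixed-effect linear
predictor. The species random effect's contribution is reported as
conditional − marginal. The regional variant adds region intercepts and
slopes; per-region combined effects are fixed estimate + conditional
mode, with 95% prediction intervals 1.96·√(se²_fixed + cond_sd²) under
the independence assumption (so the PI is never narrower than the fixed
CI). Model comparison reports both R² components for both fits and their
differences.

## Synthetic worlds

The generator emulates the structural features the pipeline cares about,
at a scale where tests run in seconds:

* **Scale**: fine grid 0.5° over a 120° × 60° window (120 × 240 cells),
  coarse factor 5. Large enough for spatial structure and ~1000+ model
  observations; small enough for sub-second generation.
* **Land** (default fraction 0.35): a Gaussian-smoothed noise field
  thresholded at the matching quantile, giving contiguous landmasses with
  coastline; elevation is a second smooth field rescaled to [0, 2500 m]
  on land.
* **Covariates**: smoothed standard-normal fields (length scale 800 km)
  mapped through exp(log median + log-sd·z) for the two densities and
  100·logistic(loc + scale·z) for cropland. The marginal parameters
  (medians 7 and 4 per km², log-s.d. 1.4/1.35; cropland loc −3, scale 2)
  approximate global rural-population (~19 ± 48 people/km²), cattle
  (~10 ± 26 head/km²) and cropland (~12 ± 19%) summary statistics.
* **Species** (default 10): unions of random land-centred disks, edge-
  softened by smoothing, clipped to land; ranges overlap so composite
  richness exceeds 1.
* **Contraction truth**: logit P = β₀ + b_s + xᵀβ + spatial field, with
  β = (0.18, 0.22, 0.54) for (rural, cattle, cropland) on the
  standardized scale — magnitudes in the regime reported for real
  large-carnivore contraction odds — β₀ = −0.5 (overall contraction
  ~40–45%), σ_s = 1, and an independent smoothed field (s.d. 0.8, length
  scale 800 km) on the logit scale so the RAC term has real structure to
  absorb. Contraction is drawn per species × coarse cell; a contracted
  cell loses *all* its fine historic cells (including fringe cells below
  the membership threshold, so extreme intercepts empty the range
  exactly). The z-scoring that the truth's β applies uses the
  member-cell constants the estimator will later reconstruct, making
  recovery exact in expectation.
* **Determinism**: one seed, spawned into per-component NumPy streams;
  two runs with the same config and seed produce byte-identical
  serialized outputs.

What the generator does **not** emulate: real coastline geometry and
digitization artefacts (harmonization is exercised on separate toy
fixtures), covariate–covariate correlation structure, temporal dynamics,
dispersal, abundance, and the observational biases of historic maps.
Passing recovery tests therefore demonstrate correctness of the
estimator under its assumed model family, not robustness to every
real-data pathology.

### Study designs used by the validation suite

* *Parameter recovery*: 50 worlds with land fraction 0.55 and large
  ranges (≈ 500 member coarse cells × 10 species ≈ 5000 observations per
  replicate) and **no** latent spatial field, i.e. data from the fitted
  model family. Mean relative bias of each β̂ and pooled 95% Wald
  coverage are checked. With the spatial field left on, the omitted
  spatially-correlated noise attenuates β̂ and breaks Wald coverage —
  a misspecification effect, not an estimator defect, so the
  well-specified design is the correct recovery test.
* *Null calibration*: 200 table-level simulations (18² cells, 8 species)
  with spatially independent responses, measuring coverage of zero by
  the RAC term's naive CI (see the caveat above).
* *Oracle equivalence*: RAC against an all-pairs double loop on a
  900-cell grid; coastline buffering and coarse-cell membership against
  exhaustive predicate scans on toy grids; exact equality required.

## Pipeline, configuration, reporting

A single YAML config (schema-validated; unknown keys rejected) drives the
stages harmonize → composite → model → report, over either a synthetic
block or user-supplied inputs (ASCII-grid rasters, GeoJSON polygons, a
species trait CSV). One top-level seed feeds every random stream. Each
stage directory carries a manifest with a hash of the governing config;
an unchanged rerun reuses artifacts and reproduces the report byte for
byte. The run manifest records every gap-filling choice in effect
(thresholds, transforms and their fitted constants, RAC options,
projection tag) so two runs are comparable. The report stage only reads
stage CSVs back — it never recomputes — so report values cannot drift
from the artifacts.

## Known limitations

* Naive Wald inference on the RAC coefficient is anti-conservative (see
  above); no spatial-error/CAR/SAR alternative is provided.
* Random-effect covariances are diagonal; correlated intercept–slope
  structures are out of scope.
* Centroid-containment rasterization under-represents polygons thinner
  than one cell; at 0.05° this is below the accuracy of historic maps.
* The coarse grid is a block aggregate of the geographic grid, so coarse
  cells shrink toward the poles like fine ones; statistics remain
  area-weighted, but cell counts are not equal-area samples.
* No dateline-crossing polygon repair and no ellipsoidal geodesy.
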