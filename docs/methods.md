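# Methods

This note records the modelling choices behind `vegshift`: what each stage
assumes, which parameters matter, what the synthetic landscapes do and do not
emulate, and where the design was genuinely open.

## Raster model and alignment

All stages operate on a single shared regular grid. The package performs no
reprojection or resampling: mixing resolutions (e.g. 30 m land cover with
~1 km climate) must be resolved by the caller before entry, and
`grid_io.align_check` gates every multi-raster stage. This keeps cellwise
and zonal semantics exact at the cost of pushing co-registration out of
scope — a deliberate trade, since hidden resampling is the classic source of
irreproducible area figures.

Coordinates are cell-center based. A point maps to the cell whose center is
nearest; points exactly on a boundary go to the cell with the lower row/col
index. Nodata propagates: any operation touching a nodata cell yields
nodata, and excluded cells never enter area accounting.

Rasters are single-band GeoTIFFs read and written through `tifffile` with
the standard georeferencing tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA) plus a JSON ImageDescription for the CRS label, units and
categorical code table; a plain-text ESRI ASCII grid is supported for
text-only fixtures. CRS handling is nominal (a label, not a projection
engine).

## Suitability model

The SDM is an L1-penalized logistic regression of presence cells against
background cells — the standard discriminative formulation of the
maximum-entropy SDM family. This is a re-implementation in that family, not
a wrapper around the reference Maxent software, and two consequences are
documented rather than hidden:

* **Feature classes** default to linear + quadratic terms of the z-scored
  predictors; hinge features (10 knots at training deciles) are optional.
  Threshold/product features and clamping are not implemented.
* **Percent contribution** is defined as Σ|coefficient| × feature standard
  deviation over training cells per variable, normalized to 100 — an
  analogue of Maxent's path-tracked contribution, chosen because the
  coefficient-based model family has no training path to track.

Defaults: correlation threshold 0.8 (greedy removal of the variable with the
most violating partners; ties by larger mean |r|, then lexicographically
smallest name — the final tie-break direction is a convention), background
10,000 cells (or all available), presences never in the background, 10
replicates with 10% of presences held out, optimizer capped at 10,000
iterations (non-convergence logs a warning and still returns), AUC gate
0.75, L1 penalty 1.0 (C = 1 in scikit-learn terms). The reported surface is
the best replicate's refit (highest test AUC, ties to lowest index) through
the logistic link. AUC is the Mann–Whitney statistic with ties counted 1/2,
computed from ranks.

Projection to another scenario re-standardizes features with the *training*
means/SDs and knots, so the projected surface is the fitted response
evaluated under new conditions. Soil predictors enter only the
forest/current model; the shrub model is climate-only, trained under paleo
conditions and projected to current.

## Potential vegetation and threshold

`combined = forest − shrub` is antisymmetric and lives in [−1, 1]. The
binarization threshold is the p-th percentile (linear interpolation) of
combined values at forest occurrences, p = 10 by default — a standard
training-presence threshold choice; the rule guarantees ≥ (100 − p)% of
calibration presences classify as forest, and ties (combined = threshold)
go to forest. The percentile is exposed because the choice of rule
(percentile vs sensitivity–specificity optimum) is genuinely open; the
threshold and rule are echoed in CLI metadata. Fewer than 10 calibration
points triggers a warning rather than an error.

## Degradation levels and area report

The cellwise crossing rules are: natural persistence → 0 (including forest
observed where shrub was predicted, which is not a degradation transition —
it is tallied separately as `forest_over_predicted_shrub_km2` for
transparency); predicted forest under savanna formation → 1; farming under
either prediction → 2; non-vegetated under either → 3; any unlisted class
("Other", e.g. water) is excluded from the analyzed region. The level codes
partition the analyzed cells exactly, so per-level areas sum to the region
area by construction.

`summary_stats` mixes truncation and rounding per field, matching how such
regional reports print: natural cover and forest-remaining truncate at 2
decimals, the potential fractions truncate at 1 decimal, shrubland expansion
and farming round to integers, non-vegetation is reported at 1 decimal.
Shrubland expansion is the *ratio* of current total shrubland (undisturbed
plus forest-to-shrub) to potential shrubland, ×100 — not the increment.
Zero denominators yield `None` (flagged), not exceptions.

## Hexagons and attribution

Flat-top regular hexagons on an axial lattice (column spacing 1.5·s, row
spacing √3·s) are the Voronoi cells of their centers, so cell→hexagon
assignment is a nearest-center query (KD-tree) and the lattice provably
tiles without gaps or overlap. Hexagon area is the closed form (3√3/2)·s².
Zonal means are taken over cells valid in every input grid so each retained
row is complete; hexagons with no valid cells are dropped.

The attribution model is a random-forest regression of hexagon-mean
degradation level (treated as continuous in [0, 3]) on hfp + 5 climate
predictors. Choices where the upstream protocol is unstated, fixed here for
determinism and recorded in the report metadata:

* tuning over `max_features` ∈ {2, …, 6} with 500 trees, selected by
  10-fold cross-validated RMSE on shared folds (a "bestTune" analogue; CV
  rather than bootstrap for seed-stable resampling);
* R², RMSE, MAE from the out-of-fold predictions of the selected candidate;
* importances as permutation importances computed on each held-out fold,
  averaged, floored at 0, and rescaled so the maximum is exactly 100
  (model-agnostic and less biased than impurity importance).

The regression framing (hexagon mean as response) was chosen over a modal
per-hexagon class because the mean preserves within-hexagon heterogeneity.

## Synthetic landscapes

The generator emulates the *statistical* structure the analysis assumes —
not any geography. Defaults, chosen once as the study conditions:

* 200×200 grid of 1 km² cells; 19 climate layers as standardized Gaussian
  random fields (smoothed white noise) with length scale 15 cells; layers
  18/19 mixed at ρ = 0.95 so the collinearity filter always has work to do;
  clay/sand and hfp as further independent fields; paleo layers = current +
  a smooth anomaly (amplitude 0.6, length scale 25 cells).
* True suitability `logistic(β·z)` with β = 4 on one driver layer (clim01),
  opposite signs for forest and shrub so the true potential map is the sign
  of the driver; 196 forest and 197 shrub presences sampled without
  replacement ∝ truth (taxon labels cycle through 6 forest / 8 shrub
  synthetic taxa, mirroring the indicator-assemblage sizes).
* Degradation as a per-cell multinomial with logits linear in hfp (slope 2;
  forest intercepts 0.0/−0.5/−3.0 for shrub/farming/bare against a baseline
  "stay" logit of 0; shrub intercepts −0.5/−3.0), farming split evenly into
  Pasture and Agriculture. Climate has no generative role by default, so
  driver attribution has unambiguous ground truth; a `slope_climate` switch
  adds a climate term to study confounding.

What the generator does **not** emulate: sampling bias and spatial
clustering of occurrence records, mixed native resolutions, realistic
bioclimatic covariance structure (layers are mutually independent except the
designated pair), landscape connectivity, or temporal dynamics. Passing
tests therefore demonstrate the pipeline's correctness and its ability to
recover a known signal under idealized conditions — they do not validate
conclusions about any real region.

With these defaults, occurrences sampled ∝ logistic(4z) over the whole grid
give replicate AUCs around 0.7 (background cells include moderately suitable
habitat, bounding the achievable discrimination); the AUC-gate behaviour at
≥ 0.75 is exercised on stronger-signal configurations with presences
restricted to the driver's top decile.

## Numerical conventions

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; fixed seeds reproduce every output
  bit-for-bit (background samples, splits, fields, forests).
* Percentile/threshold computations use linear interpolation; ≥ breaks ties
  toward FOREST; replicate-AUC ties select the lowest replicate index;
  tuning-RMSE ties select the smaller `max_features`.
* Degenerate inputs: all-zero SDM coefficients → uniform contributions with
  a warning; constant attribution response → error; hexagon side larger
  than the extent → single hexagon with a warning.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default 200×200 conditions (≈ 1 minute per seed on one CPU; the 5-seed
recovery check ≈ 5 minutes), and use 80×80 landscapes for module-level
integration fixtures. These sizes are the package's chosen desk-scale study
conditions; all stages scale linearly in cell count except the random-forest
stage, which scales with hexagon count.
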