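# Methods

This note documents the models, the synthetic world, the numerical choices and
the known limitations of `stacksdm`, in the spirit of a model-description
vignette.

## Scope and data model

All spatial data live on one regular lon/lat grid (`GridSpec`, corner-
registered at the lower-left cell edge; row 0 is the southernmost row).  Cell
membership is half-open — a point on a shared edge belongs to the cell whose
lower edge it touches — so boundary points are assigned deterministically.
Rasters are exchanged as ESRI ASCII grids; the writer emits full-precision
`repr` floats so write→read round-trips are bit-exact on finite cells.

Two Earth radii are used deliberately: the authalic radius (6371.0088 km,
the equal-area sphere) for all areas, via the spherical-zone formula
A = R²·Δλ·(sin φ_top − sin φ_bot), and the WGS84 equatorial radius
(6378.137 km) for "km at the equator" resolution statements.  Snapping a land
occurrence to the sea uses great-circle distance between cell centers, with
ties broken toward the smallest row-major index after rounding distances to
the millimetre (making geometric ties exact).  Planar-vs-geodesic behaviour of
GIS proximity tools varies; great-circle center-to-center is the documented
choice here.

## Model families

| family | implementation | contrast sample |
|---|---|---|
| `maxent_hinge` | L1-penalized logistic regression on hinge features (authored here; scikit-learn's liblinear solves the convex problem) | background (presences not excluded) |
| `linear_logistic` | logistic regression with quadratic terms | pseudo-absences |
| `additive_spline` | cubic B-spline basis (6 knots) + logistic link | pseudo-absences |
| `bagged_trees` | random forest, 100 trees, √p features per split | pseudo-absences |
| `neural_1layer` | one hidden layer (8 units), early stopping | pseudo-absences |

The maximum-entropy family is fitted as penalized logistic presence-vs-
background discrimination on hinge features — the standard convex equivalence
for presence-background maximum-entropy fitting.  Only a monotone suitability
score is needed downstream (every use is threshold-based), so the raw/
cumulative/logistic output transforms of MaxEnt-the-software are not
reproduced.  Hinge knots sit at the nine training deciles per predictor; each
predictor also contributes a [0, 1]-rescaled linear term.  The L1 weight is
λ = 0.02·√(n_features/n_presences) per sample (optimizer tolerance 1e−5),
chosen to match the magnitude of MaxEnt's default hinge regularization;
heavier penalties visibly flatten response curves and bias recovered optima.

Two families needed care with the 500-presence vs 10,000-contrast imbalance:

* **bagged trees** — refit training scores of a forest are essentially 0/1, so
  the training maxSSS threshold would always degenerate to 1.0.  The
  threshold is therefore computed from *out-of-bag* scores, which are honest
  training-data predictions.  Class weighting is omitted for this family
  (maxSSS is prevalence-insensitive, and weighted OOB aggregation is
  unreliable in current scikit-learn).
* **neural net** — the perceptron supports neither class nor sample weights,
  and its accuracy-based early stopping stalls at the majority-class plateau
  under heavy imbalance; presences are oversampled to parity for the training
  call only.  Evaluation and thresholding always use the original cells.

Replicate seeds derive from one master seed by SHA-256 over
(species, family, replicate), so any replicate is reproducible in isolation
and contrast-cell ordering cannot influence results (cells are canonicalized
row-major before fitting).

## Predictor screening

Contributions are permutation importance on training AUC (mean drop over four
permutations, floored at zero, normalized to 100).  Selection applies, in
order: the < 4% contribution rule; greedy resolution of |r| ≥ 0.7 pairs from
the highest |r| down, keeping the higher contribution (Pearson r on a seeded
sample of ≤ 10,000 sea cells); and the three-predictor floor.  When the floor
forces restoration of dropped predictors, candidates are restored in
decreasing contribution order, preferring ones that do not reintroduce a
collinear pair and falling back to collinear ones only if unavoidable — the
floor outranks the correlation rule on conflict.  The per-predictor jackknife
(with-only and without refits scored on held-out data) and a response-curve
shape flag (monotone / unimodal / irregular) are reported for inspection but
do not act as automatic filters: judging whether a response "behaves
biologically" is left to the analyst.

Permutation importance is winner-take-all when one predictor (typically
depth, for shelf-bound species) nearly saturates global presence-background
discrimination; secondary refiners can then legitimately score under 4%.
This is a real property of contribution-style screening, not an artifact —
users with strong priors should shape the candidate list accordingly.

## Evaluation and ensemble

AUC is the rank-based Mann–Whitney estimator (ties 0.5).  TSS =
sensitivity + specificity − 1 holds as an exact identity in every report.
Thresholds come from *training* data (maxSSS over the unique observed scores,
smallest on ties); evaluation statistics from *test* data; the evaluation
contrast set is the family's own held-out contrast sample.  Replicates with
TSS < 0.7 **or** sensitivity = 0 are excluded (the disjunctive reading; the
conjunction is a config switch).  Future-scenario binaries reuse each
replicate's present-fitted threshold — fitted models are projected, never
re-thresholded.  Consensus is majority-within-family then majority-across-
families, with ≥ 0.5 counted suitable both times (precautionary tie for a
risk-screening product).  Depth masking (suitable cells deeper than the
species' maximum depth set to 0; phytoplankton exempt) commutes with
averaging because the mask is replicate-independent, and is applied to the
consensus map.

## Hotspots and change accounting

Richness is the cell-wise sum of species binaries.  Jenks natural breaks are
computed by an exact weighted Fisher dynamic program on the distinct values
(equivalent to exhaustive partition search; default k = 5, reduced with a
warning when fewer distinct values exist).  Zero-richness cells are excluded
from category areas — the categories describe suitable habitat only.  Change
categories (gain 0→1, loss 1→0, two stable classes) partition the analysis
mask exactly, so gain + loss + stable areas re-sum to the mask area to
rounding error; net percentage change is area-weighted, with a zero present
area reported as NaN rather than an error.  Group aggregates use the union of
member binaries (cumulative-risk semantics, consistent with stacked
richness); a mean-of-species alternative is available via
`group_summaries(..., aggregation="mean")`.  Per-category net percentages are
computed on areas (not cell counts).  Species with native ranges inside the
analysis extent are retained in richness by default.

## The synthetic world

`make_scenarios` builds a present stack of eight predictors (SST, bottom
temperature, surface/bottom salinity, ice thickness, depth, land distance,
iron) on a 0.5° global grid by default (360 × 720; any grid is accepted —
the test suite uses 1° for speed, and those scaled runs are what the test
documentation reports).  Land is a fixed set of analytic continents; SST
falls smoothly from equator to poles with a longitudinal wave and seeded
Gaussian noise; ice thickness is 1.2·max(0, −0.5 °C − SST); bottom
temperature relaxes to 1.5 °C with an e-folding depth of 1200 m; depth rises
from abyssal plains to broad continental shelves on a cubic ramp; iron
combines coastal runoff with longitudinal basins so that no predictor is a
deterministic function of another.  Future scenarios add spatially uniform
anomalies (+1.2 °C by 2050, +2.4 °C by 2100 — an intermediate stabilization
pathway) to both temperature layers and regrow ice from the warmed SST;
salinity is carried over unchanged by default and depth/land distance are
scenario-invariant.  The pan-Arctic extent is sea at ≥ 60°N.

Truth niches are products of per-predictor responses — Gaussian, logistic, or
a tolerance *window* (product of rising and falling logistic edges).  The
default roster holds eight cool-water species, two per ecological group
(zoobenthos, phytobenthos, zooplankton, phytoplankton), with window-shaped
thermal tolerances whose warm edges sit above present Arctic temperatures.
Three properties were designed in deliberately: truth suitability is close to
binary (strong environmental determinism, so maxSSS range maps are comparable
to the truth region {S* ≥ 0.5}); each truth region is comfortably larger than
the 500-presence draw (occurrences are sampled without replacement with
probability ∝ S*, and a too-small region would force draws into
low-suitability tails); and every species gains pan-Arctic habitat under
warming, giving the change analysis a known directional signature.
Occurrences get optional within-cell jitter and an optional land-contamination
fraction to exercise the snap-to-sea conditioning.

What the generator does *not* emulate: spatial sampling bias and survey
effort, occurrence misidentification, predictor measurement error correlated
in space, ocean dynamics (currents, fronts), dispersal limitation, and
CMIP-style spatially structured climate anomalies.  Passing tests therefore
demonstrate that the machinery is correct and recovers known signal under
clean conditions — not that real-data predictions inherit this accuracy.

## Reproducibility and problem sizes

One master seed drives everything through stable SHA-256 derivation; rerunning
any stage with the same config yields byte-identical tables, and the run
manifest records per-file checksums (`stacksdm verify`).  The test suite
exercises the full pipeline at 1° (eight species × five families × five
replicates, ~2 minutes); the acceptance script fits the same roster at the
default 0.5° grid, skipping only full-grid map prediction (its quantities
need held-out statistics, not maps) and the informational jackknife.

## Known limitations

* The ASCII raster format is the only I/O format; no GeoTIFF/shapefile
  support, no projected coordinate systems, no ellipsoidal areas.
* MaxEnt-the-software's internal iteration scheme and percent-contribution
  accounting are intentionally not reproduced; contributions here are
  permutation-based and tool-independent.
* Land-distance uses a planar distance transform scaled by latitude — adequate
  for a synthetic predictor, not for navigation-grade distances.
* The BIOCLIM envelope family is deliberately absent (known-poor performance).
* Richness maps count species independently; no biotic interactions.
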