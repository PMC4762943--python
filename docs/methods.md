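# Methods

This note records the models implemented in `shelfshift`, the
assumptions they make, the defaults and why, and what the synthetic
tests do and do not establish.

## Data model and temporal scheme

The canonical containers are two tidy tables: hauls (one row per tow
with year, season, region, position, depth, SST, BT, stratum) and
catches (haul, species, biomass ≥ 0 in kg per standardized tow; hauls
missing from the catch table are implicit zeros). Rows violating
invariants (non-positive depth, unknown haul ids, out-of-range years)
are dropped and counted, never silently imputed.

The series 1968–2012 is split two ways: four roughly decadal periods
(1968–1978, 1979–1989, 1990–2000, 2001–2012) used to define
assemblages and first/last shift vectors, and nine contiguous
five-year blocks (1968–1972 … 2008–2012) used for centroid time
series; block midpoint year is the regression abscissa. The
rare-species filter (default: positive biomass in ≥ 10 distinct years)
is applied per region, because every downstream analysis is regional;
whether to scope it per season as well is configurable but off by
default.

## Niche clustering

A species' niche vector in a period is the biomass-weighted mean of
depth, SST, and BT over its positive hauls. Features are z-scored
within region/season/period before clustering (config switch):
without scaling, depth in meters numerically swamps temperatures in
°C and the temperature structure of the assemblages would be
invisible. Two methods are run — k-means (25 restarts, best
within-cluster SSE, seeded) and complete-linkage hierarchical
clustering on Euclidean distances — and labels are renumbered so mean
cluster depth increases with label (ties broken by mean BT). This
depth-ordering doubles as the cross-method and cross-period label
alignment, so no combinatorial matching is needed. Internal validation
reports connectivity (nearest-neighbour penalty, L = 10 neighbours),
compactness as the mean within-cluster pairwise distance, the Dunn
index (reported alongside because "compactness" is ambiguous between
the two in common usage), and mean silhouette width.

"Core" species are those given the same depth-ordered label by both
methods in at least three of the four periods; an assemblage is the
set of core species sharing a label. This per-species rule is
deterministic and reproduces the intended "grouped together in both
methods" semantics without building co-membership graphs.

## Shift geometry

Positions are re-gridded onto a shelf-following polyline: along-shelf
distance = cumulative distance to the orthogonal projection, cross-
shelf = signed perpendicular offset (positive to the right of the
axis direction, i.e. offshore for a coast-left axis). Projection uses
a per-segment equirectangular plane (longitude scaled by cos
latitude), which is sub-km accurate at the ~100 km scales involved and
exactly invertible for points with an interior orthogonal projection;
points in convex corner wedges or beyond the ends are clamped to the
nearest vertex and flagged. Biomass-weighted centroids are computed in
this space and mapped back, which keeps them inside the surveyed
corridor; latitude and depth centroids are also computed directly as
weighted means, and those are what the latitudinal (°N/yr) and depth
(m/yr) rates regress.

Shift vectors between decadal periods 1 and 4 use the haversine
distance and initial great-circle bearing on a sphere of radius
6371.0 km. Within-assemblage bearing concentration is tested with
Rayleigh's test: mean resultant length R̄, statistic z = nR̄², and the
standard small-sample approximation
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)) with R = nR̄; a Monte-Carlo
p (uniform-resampling oracle) is available and agrees with the
approximation to < 0.01 for n ≥ 20. Both R̄ and z are emitted because
published "z" values in this literature are sometimes resultant
lengths; the self-consistent definitions above are what the tests
target.

Centroid trends use OLS by default. Where the sampled domain cuts off
a species' distribution at a known bound, a truncated-normal
regression (maximum likelihood, BFGS, Wald SEs from the inverse
Hessian) is provided; with the bound far from the data it reduces to
OLS (verified to 1e-4), and under genuine truncation it moves the
slope back toward truth where OLS attenuates. Species need centroids
in ≥ 6 of 9 blocks (configurable) to enter trend regressions.
"Deepening" is flagged when the depth slope is positive with p < 0.05
over the full block series.

## Delta-lognormal thermal envelopes

Trawl catches are zero-inflated, so each species' envelope is a
two-part model: a binomial GAM (logit link) for presence and a
Gaussian GAM for log positive biomass. Both use penalized B-spline
smooths of SST and BT (basis dimension 5 per term by default — small
deliberately, matching the smooth unimodal responses the generator
produces and keeping hundreds of fits cheap; penalty weight α = 1,
both configurable) plus two parametric terms: habitat stratum
(strata with < 5 positive hauls pooled into the baseline) and the
species' mean annual region-wide biomass per haul, which absorbs
region-wide abundance trends (e.g. exploitation) so the smooths
capture the thermal response. Both submodels carry both parametric
terms. A species present in every haul gets a constant presence
component equal to 1, in which case the delta prediction equals the
lognormal-mean prediction exactly.

The per-haul weight is the delta-lognormal mean p̂·exp(μ̂ + σ̂²/2).
The lognormal variance correction is inert for centroids (σ̂ is
constant per species, and weights enter only relatively within a
block) but is fixed for reproducibility of the weight values
themselves. Prediction covariates are clamped to the 1st–99th
percentile of each submodel's own training values (the two submodels
have different spline supports) and clamp counts are recorded.

Envelope centroids are prediction-weighted mean latitude and depth
over each block's actual hauls — not a regular grid — so the centroid
responds to where suitable temperatures were located in that block.
Their slopes against block midpoint year are the taxon-specific
climate velocities, paired with the observed slopes for the same
species; observed-vs-predicted agreement is summarized by OLS (slope,
r², deviation from the 1:1 line), and velocity differences between
assemblages by tie-corrected Kruskal–Wallis tests applied separately
to the latitudinal and depth velocity sets per region/season.

## Habitat area and the mixed model

Haul positions are projected with a spherical Lambert azimuthal
equal-area transform centered on the region's mean position (areas in
km² by construction). Two weighted Gaussian product-kernel densities
are built per assemblage/season/region/block: biomass-weighted (where
the assemblage was) and envelope-prediction-weighted (where its
thermal habitat was; species predictions are summed raw). Bandwidth
is Scott's rule per axis on the weighted points with a 5 km floor;
the grid (2 km cells by default) is padded three bandwidths beyond
the points and weights are normalized before smoothing, so the field
integrates to ~1 and core areas are invariant to uniform weight
scaling. The "core" area is the count of cells whose density exceeds
the mean + 1 SD, times cell area; the thresholding statistics are
computed on the density surface over cells within 25 km of a data
point, so empty ocean does not dilute the mean and SD. Cell counting
at ≤ 2 km resolution replaces polygonization of the level set — an
equivalent, resolution-controlled estimator (verified within 5% of
the closed-form super-threshold ellipse of a Gaussian field at 1 km
cells).

The area model is a linear mixed model, kernel area on thermal area
and total biomass with random intercepts for region and season nested
in region, fitted by REML with Wald t statistics; a singular nested
fit falls back to a region-only intercept with a warning. Predictors
stay on their natural scale (km², kg); a standardized variant is
available for conditioning.

## Synthetic generator and ground truth

The generator emulates the analysis' target system, not its
hydrography: two rectangular domains — a semi-enclosed north with deep
basins and a cool southwestern corner (regional gradients point
cool-to-southwest, plus an optional localized Gaussian cool pocket),
and an open south shelf whose depth grows offshore and whose
temperature falls toward the northeast. Temperature fields are linear
in position with a secular warming rate (default 2 °C across the
45-year series; the implied latitudinal isotherm velocity is
warming rate / latitudinal gradient). Species have separable Gaussian
niches in depth/SST/BT (occupancy = p_max times the product kernel;
positive biomass lognormal), so distribution shift *emerges* from the
moving field rather than being imposed. For linear fields the expected
centroid drift is analytic: differentiating the suitability
stationarity condition in time gives a 2×2 linear system whose
solution is the (°N/yr, m/yr) truth used by the recovery tests; it
covers SST-trackers, BT-trackers, depth-compensators and mixed cases.
The cool pocket is nonlinear and excluded from that truth — pocket
scenarios are checked qualitatively (bearing quadrants) instead.

Scale defaults are desk-scale study conditions: 70 hauls per year per
region (~3·10³ per scenario), four assemblages of six species per
region, haul positions uniform over the domain each year (the real
design is stratified-random; uniform is sufficient for testing the
estimators), and environmental measurement noise of 0.3 °C. In the
velocity-recovery scenario (prescribed 0.05 °N/yr SST isotherm
velocity, with BT on a steeper gradient giving 0.033 °N/yr
BT-trackers and temperature-insensitive depth specialists at 0),
niche centers are placed so each species' range stays inside the
sampled domain for the whole series: a range cut off by the survey
edge attenuates the recovered slope — a domain-truncation effect the
truncated-regression option exists to address, not an estimator
property, so the recovery experiment avoids conflating the two.

What passing these tests shows: the estimators recover known shifts,
calibrated test levels, cluster structure, and the generative area
model under clean Gaussian-niche, linear-field conditions. What they
do not show: behaviour under gear/vessel effects, stratified sampling,
seasonal migration within a year, non-separable niches, or real
hydrography — conclusions about real survey data still require the
usual diagnostics.

## Numerical and design choices

- Randomness: one global seed, expanded into per-stage substreams by
  hashing stage labels (stable, < 2³¹), so stages can be re-run in
  isolation; every pipeline output is byte-identical under an
  identical config + seed, and the output manifest records the config
  hash, seed, and a digest per table.
- Degenerate inputs: identical niche vectors flag a degenerate
  silhouette instead of raising; a constant density field yields core
  area 0 and a degeneracy flag; identical centroids yield a
  zero-distance shift vector with an undefined bearing flag; groups
  of size < 2 are dropped from Kruskal–Wallis with a warning.
- Null calibration: under a stationary climate the velocity CI
  exclusion rate measures ≈ 5–8% at the 95% level — mildly
  anticonservative because block-level centroid errors share the
  fitted envelope surface and haul set; within a single simulated
  world, species' errors are correlated (they share hauls), so
  calibration statements pool several independent worlds.
- The pipeline's default two-region world makes no attempt to make
  assemblage range area independent of biomass, so its own area-model
  fit is descriptive; the mixed model's inferential behaviour is
  established on the generative experiment (area = β1·thermal + noise,
  biomass independent), where it recovers the thermal driver and the
  permutation control holds at the nominal level.
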