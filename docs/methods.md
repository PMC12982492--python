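# Methods

## Problem

Climate warming displaces isotherms; species track them (or fail to). A
*climate velocity* field assigns every grid cell a horizontal displacement
rate (km/yr) of the local iso-temperature line between two periods. The
package implements two estimators of that field, derives species
range-shift velocities from observation records by geodesic centroid
tracking, and quantifies how well each estimator predicts the observed
shifts, per axis (longitude, latitude, elevation/depth).

Because the real observational stack (continent-scale winter bird counts,
trawl-survey presence records, reanalysis temperature, a global DEM) is
large and access-restricted, the package ships a synthetic-data generator
that reproduces the *statistical structure* the analysis relies on. All
tests and the acceptance script run offline on that generator.

## Climate-velocity estimators

### Gradient method

For a scalar field ψ (temperature), the classical velocity index is the
ratio of the temporal rate of change to the spatial gradient magnitude,
directed down-gradient:

    v = (∂ψ/∂t) · (−∇ψ) / ‖∇ψ‖²

so warming on a poleward-cooling field yields a poleward vector. ∂ψ/∂t is
the difference of the two decadal means divided by the offset of the
window midpoints; ∇ψ is evaluated by central differences on the *initial*
decadal mean (edges one-sided). Which period the published gradient
implementations differentiate is ambiguous; the initial field is used
here, consistent with "the velocity experienced at the start of the
shift", and the choice is isolated in one function.

Where ‖∇ψ‖ vanishes the ratio blows up. Cells with ‖∇ψ‖ below `min_grad`
(default 1e-4 °C/km; no canonical value exists, this is deliberately tiny
relative to the ~1e-2 °C/km synthetic gradients) are masked invalid and
set exactly to zero, so the output is finite everywhere by construction.

### Monte-Carlo iterative convergence (matching) method

The second estimator treats velocity estimation as a regularized
registration problem. A per-node displacement field D (km), initialized
to zero, is refined by greedy stochastic descent on

    E(D) = misfit(D) + λ · shear(D)

* `misfit` backward-warps the initial field: ψ₀ is sampled bilinearly at
  node − D (clamped to the nearest edge outside the grid) and compared to
  ψ₁ at the node, summing squared residuals. D is therefore the forward
  displacement of the pattern; the sign convention is pinned by a test on
  the parallel scenario (warming ⇒ northward D).
* `shear` sums ‖D(i) − D(j)‖² over 4-neighbour pairs, with displacements
  divided by the mean cell size. The normalization makes the penalty
  dimensionless, so λ does not depend on grid resolution or on the °C/km
  scale of the data. Boundary nodes simply have fewer pairs (the domain
  is a bounded region, not the whole sphere).

Each iteration perturbs one uniformly chosen node's displacement by an
isotropic Gaussian step and keeps the move iff E strictly decreases
(greedy; no annealing temperature, matching the accept-if-better contract
of the published algorithm description). The step standard deviation is
drawn log-uniformly between 2% and 100% of `proposal_scale` cell sizes:
a single fixed scale either stalls against the shear penalty (large
steps) or crawls (small steps), while the multi-scale mixture lets the
descent take coarse steps early and fine steps near the optimum. The loop
stops at `iteration_budget` proposals or after `stall_limit` consecutive
rejections, and returns D/Δt.

Defaults — λ = 0.5, proposal scale 0.25 cells, budget 400 × nodes, stall
limit 20 × nodes — were calibrated once on the two reference scenarios
(30×30 nodes): parallel isotherms converge to within ~3% of the b/a
closed form in ~4 s, and the curved scenario reaches ~2% of its initial
misfit. Larger λ trades fidelity for smoothness; λ = 1 leaves the
parallel-scenario median error at ~12%. All four knobs are exposed in
`MatchConfig`. Exact numerical agreement with the original authors'
implementation is not claimed: their hyperparameters and proposal law are
not public; this loop honors the verbal contract (random local
deformations, accept iff the fields match better, shear-penalized).

Guaranteed properties (tested): the accepted-move objective sequence is
strictly decreasing; identical seeds give bit-identical fields; identical
input fields return exactly zero velocity.

## Geodesy

All horizontal distances use one spherical constant, K = 111.195 km per
degree (mean radius 6371 km): north km = K·Δlat, east km =
K·cos(lat)·Δlon. The same metric serves the gradient conversion, the
matching displacements, centroid shift vectors and the synthetic
advection, so kilometre quantities are directly comparable across
modules; the ellipsoidal correction (< 0.5% at continental scale) is far
below the noise of interest.

The geodesic mean position of a weighted point cloud is computed as the
weighted mean of unit position vectors renormalized to the sphere,
followed by an intrinsic-mean (Karcher) refinement that minimizes the
weighted sum of squared great-circle distances. The refinement matters:
for skewed weights on clouds tens of degrees across, the raw chordal mean
deviates from the true geodesic mean by > 0.1°, which is the same order
as a decade of range shift. With the refinement the centroid agrees with
brute-force minimization to ~1e-7°.

## Species range shifts

Inclusion criteria (counting surveys / birds mode): a species is kept iff
it has ≥ 5 reports in *every* year of both decades; a (species, site)
pair is kept iff the site reports the species every year with ≥ 2
observations. After dropping failing sites the ≥ 5/year species rule is
re-checked on the surviving records by default (`recheck="pre"` restores
the raw-count species set; the interaction of the two rules is not
pinned down by any convention we know of, so both are available).
Presence surveys / marine mode: species-level only, ≥ 3 observations per
year, no site rule. Both filters are verified against brute-force
nested-loop oracles on engineered fixtures.

Centroids: yearly weighted geodesic centroids (weights = individual
counts in birds mode, unit weights in marine mode), then the unweighted
geodesic centroid of the yearly positions per decade. The offset between
two decade centroids, divided by the offset of the window midpoints
(consecutive decades ⇒ 10 yr), gives the shift vector; it is decomposed
into longitudinal/latitudinal components with the K metric, a heading
(degrees clockwise from north, undefined at zero magnitude), and an
elevational velocity from bilinear DEM samples at the two centroids
(signed elevation, depths negative: deepening is a negative rate).

## Comparison statistics

Climate velocity "experienced" by a species is the field vector at the
grid node nearest its initial-decade centroid (nearest node, not
interpolation, so masked-invalid zeros do not bleed into neighbours). The
climate elevational velocity displaces the centroid along the climate
vector over the full decade interval by default (`per_yr` optional) and
differences the DEM.

* Per-decade fits: OLS of species component on climate component
  (intercept included by default; a through-origin option exists), with
  outliers removed at 1000 km/yr on either horizontal side. The threshold
  is not applied to the elevational component (its natural scale is m/yr;
  a separate elevational threshold is configurable, default none).
* Aggregated decades: linear mixed model with a species random intercept,
  fitted by maximum likelihood; reported statistic is z = slope/SE with a
  normal two-sided p. When every species contributes a single row the
  intercept variance is unidentifiable and the fit degenerates to pooled
  OLS, returned with `converged=False` rather than an exception or a
  garbage standard error.
* Cross-axis check: joint OLS of one species component on all three
  climate components, with a rank-deficiency flag.
* Headings: differences wrapped to [−180, 180); circular mean and
  sd (√(−2 ln R̄)) over defined headings only; rows with undefined
  headings are excluded, not imputed. No multiple-testing correction is
  applied anywhere.
* Regional splits: a configurable meridian (default −100°) labels rows
  west/east.

## Synthetic generator

Temperature scenarios share a base field ψ = ψ₀ − a·d(lat) + b·t with
a = 0.01 °C/km and b = 0.02 °C/yr by default (so the closed-form velocity
b/a = 2 km/yr north, a realistic decadal-scale displacement rate):

* `parallel` — exactly the closed form; both estimators must agree.
* `curved` — adds c·sin(k·lon) (c = 2 °C, k = 0.4 rad/deg), bending the
  isotherms while their true drift stays a uniform northward shift: the
  optimal deformation is on-grid and shear-free, so the matching
  estimator can in principle drive the misfit to zero, while the gradient
  estimator tilts and attenuates.
* `flat_patch` — gradient exactly zero inside a disc, exercising the
  blow-up guard.
* `composite` — curved isotherms plus longitudinally modulated warming
  b(lon) = b·(1 + 0.5·sin(0.2·lon)), so the true displacement varies in
  space and regressions against either field are non-degenerate.

DEMs: flat, linear slope (5 m/km default), or a tent ridge.

Species: each species starts uniformly in a configurable box; every year
a cloud of 8 sites is drawn i.i.d. Gaussian (sd 20 km default, the scale
of a large survey circle cluster) around the true centroid, with 2
observations per site-year and Poisson counts (mean 10, clipped ≥ 1) in
birds mode, or 4 presence records per year in marine mode. The centroid
then advances by s·v + β, where v is the prescribed vector or the nearest
node of a velocity field, s ∈ [0, 1] is the tracking factor and β a
per-species constant velocity bias (the random intercept recovered by the
mixed model). Configurable fractions of species (and of sites) are
under-reported in the first year so every inclusion rule has genuine
negative cases. One seeded generator drives everything; equal seeds give
byte-identical CSVs.

The generator does not emulate observer-density bias, coastline-shaped
survey regions, or interannual climate variability around the secular
trend. Passing tests therefore demonstrate correctness of the estimators
and statistics under the stated model, not robustness to those real-data
pathologies.

## Problem sizes

The reference scenarios use 30×30 to 31×51 grids, 10-year windows over
1960–1990, and 50–100 species; the matching estimator converges in
seconds at these sizes and the full test suite plus acceptance script
complete in a few minutes. All sizes are plain parameters; nothing in the
implementation assumes them.

## Known limitations

* Centroid tracking summarizes a whole range by one point; leading/
  trailing edge dynamics are out of scope.
* The matching estimator's solution is unique only up to the shear/misfit
  trade-off; λ is a modelling choice, not an estimated quantity.
* Regional masks are half-plane splits by one meridian; arbitrary
  polygons are not implemented.
* The pipeline advects synthetic species with the velocity field of the
  first decade pair; a time-varying advection would require per-year
  fields of velocities, which the estimators do not produce.
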