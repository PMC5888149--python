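# Methods

This note documents the models, algorithms and numerical choices in
`pyrodiv`, the assumptions behind the synthetic-landscape generator, and
the limits of what the validation studies show.

## Grid, dates and formats

The analysis grid is a regular lon/lat lattice of 0.5° cells (the
half-degree "quarter-degree square" scale at which richness atlases are
commonly compiled), each subdivided into 10 × 10 pixels (~0.05°, the
scale of a burned-area product pixel). Distances and areas use a fixed
planar scale (111 km/degree) carried in the grid metadata, so no
geodesy enters any computation; for real geographic data a local
equal-area projection should be applied upstream. Dates are integer
days since 2000-01-01 everywhere; the per-year burn "layers" are a
storage partition only and impose no constraint on dates. Rasters are
read and written as ESRI ASCII grids (plain text) — an intentional
choice of a text raster dialect with the same per-pixel semantics as
the GeoTIFFs a satellite workflow would use; polygons travel as
GeoJSON, tables as CSV, generator truth as JSON.

## Fire delineation

Burned pixel-observations (pixel × burn date) are partitioned by
connected components of the graph whose edges join spatially adjacent
(or identical) pixels with burn dates at most `date_gap_days` apart.
Defaults: 8-connectivity, 8-day gap (the compositing period of monthly
burned-area products); both are flags, since published continental-scale
delineations do not state their constants. Because
grouping is a chain rule, a long-running fire is one event as long as
each adjacent link is within the gap. The partition is provably
order-independent (it is a connected-components computation); fire ids
are assigned by (earliest date, position) so they are reproducible too.

Attributes:

- `logArea = ln(n_pixels × pixel_area_km2)`. Natural logs everywhere;
  no base is conventional and effects are scale-free after
  standardisation.
- `fireday`: the signed circular difference between the fire's earliest
  burn date and the 15th of the cell's wettest month, minimised over
  the adjacent calendar years, in [−182, +183], positive after the
  peak, ties resolved to the positive branch.
- `logFRI`: ln of the mean, over the fire's pixels with at least one
  earlier burn, of days since that pixel's most recent earlier burn.
  Undefined (NaN, not an exception) when no pixel burned before.
- `logFRP`: ln mean radiative power of the detections falling inside
  the fire's footprint within [ignition − 2 d, last burn + 2 d]. A
  detection eligible for two fires (possible after padding) goes to the
  fire whose burn date at that pixel is nearest; ties to the earlier
  fire id.

Fires missing FRI or FRP are dropped from the fire table (both data
streams are required), with exclusion counts logged. A fire is assigned
to the cell containing its footprint centroid, so each fire is counted
exactly once.

## Pyrodiversity index

Attributes are normalised by their standard deviations computed over
the *entire* fire table (global, not per-cell), so cell volumes are
comparable across the map. Cell pyrodiversity is the convex-hull volume
of its fires' normalised 4-D points with an additive bootstrap bias
correction, `max(0, 2·V_obs − mean(V_b))`, B = 200 by default. The hull
of a finite sample under-covers the support of the underlying
distribution, so V_obs is biased low in small cells; the bootstrap
estimates that bias as `mean(V_b) − V_obs` and subtracts it. A
rarefaction mode (mean hull volume of fixed-size subsamples) is
provided behind a flag as an alternative sample-size standardisation;
the exact correction scheme used at continental scale is not published,
so both are labelled assumptions. Cells with fewer than `n_min = 10`
fires get a missing index — 4-D hulls on fewer points are dominated by
degeneracy (the hull volume of < 5 points is exactly zero).
Resampling is seeded per cell from (seed, cell id) over fires sorted by
fire id, making the index invariant to fire-table row order.

Attribute means are reported on their stored scales (logged where
logged). CVs are taken on positive raw scales — area in km², FRI in
days, FRP in MW — because a CV of a signed or logged quantity is not
well defined; the fireday CV is the circular SD of ignition day-of-year
divided by 365. There is no single convention for the scale on which
attribute CVs are taken; this choice is documented and isolated in one
function.

## Cell covariates and richness

MAP is the sum of the 12 monthly climatology means; the peak month is
the argmax (earliest on ties). Wet savanna is MAP > 650 mm yr⁻¹ — the
rainfall level above which fire, rather than water, begins to limit
woody vegetation structure — and the savanna domain is MAP ≥ 300 mm
yr⁻¹ (a rainfall-floor stand-in for a vegetation-map mask; a user mask
can override). NPP is averaged over years then pixels; topographic
heterogeneity is the SD of pixel elevations in the cell (the metric is
not standardised in the literature; SD-of-elevation is the assumption
here). Protected-area coverage is the areal fraction of the cell under
the PA union, and the analysis set is savanna cells with coverage
≥ 0.5. Species are counted present in a cell when their range polygon
intersects it with positive area. Mammal partitions: bats by flag;
small/large mammals split at the median body mass (ties inclusive-low,
so identical masses all land in "small"); common species are the 50 %
most widely distributed (range size in cells, ties inclusive-high);
birds are partitioned into all/common only. Medians are computed on the
species pool after clipping ranges to the grid.

## The spatial richness model

Likelihood: counts are Poisson with log link; the linear predictor adds
an intrinsic CAR field φ (Besag, queen adjacency, sum-to-zero per
connected component, islands pinned at 0) and iid cell noise ε.
Richness-atlas analyses rarely commit to a likelihood family;
Poisson-lognormal is the natural choice for overdispersed counts, and a
Gaussian mode is available behind a flag (also used for conjugate
validation). Fixed effects: intercept; cubic B-spline of standardised
NPP with two interior knots at the terciles (a "two-knot GAM" fixes
neither degree nor placement; the first basis column is dropped against
the intercept); standardised topographic heterogeneity; a wet
indicator; and per-stratum fire-covariate columns c·1[wet], c·1[dry] —
the interaction parameterisation that reports the wet and dry slopes
directly. The quadratic variant appends squared standardised
covariates, also stratified. Means-class and CV-class covariates are
never mixed (they are strongly correlated). A stratum with fewer than
10 complete cells makes the interaction inestimable and raises an
error; cells with missing covariates are dropped listwise with logged
counts.

Priors: Normal(0, 10²) on fixed effects (standardised scale);
Gamma(0.1, 0.5) on both random-effect precisions — equivalently a
log-gamma(0.1, 0.5) prior on the log precision, the vague spatial-effect
prior conventional in CAR models of this kind, near-flat over the
relevant range.

Inference is by MCMC rather than the integrated nested Laplace
approximation (INLA) such CAR models are often fitted with — the
contract is posterior quantiles, not an algorithm. The sampler is a
blocked Gibbs scheme: (1) per-cell log-rates η update by vectorised
random-walk Metropolis (independent across cells given β, φ), with
per-cell step sizes adapted toward 0.44 acceptance during burn-in only;
(2) β | η is Gaussian-conjugate; (3) φ | η is a GMRF draw through a
dense Cholesky of τ_φ(D − A) + τ_ε I, then recentred (the sum-to-zero
constraint); (4) both precisions are Gamma-conjugate. In Gaussian mode
step (1) disappears. Defaults are 2 chains × 4000 iterations with 2000
burn-in; split-R̂ is computed for every reported parameter, and a fit
with any R̂ ≥ 1.05 (or a single chain) is returned flagged
`converged = False`, never silently. wAIC is −2(lppd − p_waic) with
p_waic the summed posterior variance of the pointwise log-likelihoods,
computed conditional on the latent fields (the conditional-likelihood
convention common in latent-Gaussian model comparison).
Predicted-richness curves evaluate the fixed-effect predictor over a
covariate grid at the stratum's mean design row with φ and ε at zero,
back-transformed through the link, with bands from the posterior draws.

## Protected-area contrast

For each PA, inside cells have ≥ 50 % coverage by that PA; outside
cells have ≥ 20 % of their area in the PA's 100-km buffer ring and are
not inside any PA (whether the original buffer cells excluded other
PAs' interiors is unstated; exclusion is the default here). Each metric
is fitted with a Gaussian random-intercept model by REML: for a fixed
variance ratio λ = σ²_PA/σ²_resid the GLS coefficients and profiled
residual variance are closed-form via the Woodbury identity per group,
leaving a bounded 1-D minimisation of the REML deviance over log λ,
with the λ = 0 boundary checked explicitly (singular fits are returned
flagged, with β and SE equal to their OLS values). Inside is coded 1,
so β_status is the inside-minus-outside difference.

## The synthetic landscape

The generator's role is to provide inputs with the qualitative
structure of the real system and a recorded truth. Rainfall is a smooth
field (trend + Gaussian random field) spanning 300–1400 mm yr⁻¹,
skewed so the 650 mm threshold falls near the median cell; monthly
climatology is a wrapped von-Mises profile around a spatially drifting
peak month. NPP is a saturating monotone function of rainfall with
multiplicative noise; elevation is an independent smooth field. Fire
frequency rises with rainfall (3 → 6 fires per cell-year) while the
spreads of season (circular SD 95 → 20 d), size (lognormal σ 1.3 → 0.4)
and intensity (σ 1.2 → 0.4) shrink — the configuration that makes the
computed pyrodiversity index decline with rainfall above 650 mm, the
qualitative gradient the index is known to show; no quantitative
fire-regime distributions are published, so the defaults are calibrated
to direction, not magnitude. Fires grow by stochastic region-growing
from an ignition pixel with per-pixel dates spread over up to 6 days,
so multi-day fires exercise the date-gap rule; a pixel burns at most
once per year layer. Detections are per-burned-pixel Bernoulli thinned
(rate 0.9) with lognormal FRP. Richness counts are drawn from exactly
the model family the inference fits, with defaults (0.09 wet, 0.03
dry, on the per-SD log scale) of the size reported for continental
wet/dry pyrodiversity effects. Species ranges are rectangles whose
centres follow a sharpened target-richness distribution via systematic
sampling (400 species, ~20 % bats, lognormal masses), giving implied
richness that rank-correlates > 0.8 with the target; protected areas
are disjoint cell-aligned rectangles covering < 50 % of the grid.

What the generator does *not* emulate: sensor artefacts (cloud gaps,
false detections beyond uniform thinning), real range-map geometry,
vegetation-map savanna boundaries, human land use outside PAs, or any
absolute calibration of fire-regime parameters. Passing recovery tests
therefore demonstrates the pipeline's internal correctness — that the
estimator recovers effects when data are generated under its
assumptions at these spatial scales — not that the continental
estimates themselves are reproduced; the published headline
coefficients derive from data this package deliberately does not
download.

## Validation studies and problem sizes

The bundled studies (also run by `scripts/acceptance.py`) use reduced
problem sizes chosen as the smallest at which each property is stably
measurable: hull geometry against exact values and a 10⁶-draw
Monte-Carlo membership oracle (membership via Delaunay location,
independent of the facet-based volume); bootstrap bias reduction over
100 hypercube replicates at n ∈ {20, 50, 100}; flood fill against an
all-pairs union-find on 5 × 5 rasters; wet/dry effect recovery on
20 × 20-cell landscapes over replicate seeds with short adaptive chains
(2 × 1600, burn-in 700 — adequate mixing for 95 % quantiles at ~400
cells); wAIC selection on 12 × 12 landscapes; GLMM recovery over 50
replicates with a 2001-point deviance grid as the optimiser oracle; and
a bit-reproducibility run of the full pipeline. Every source of
randomness descends from one `SeedSequence`, so all studies are exactly
reproducible.

## Known limitations

- The Metropolis step on η mixes more slowly as counts grow very large
  (the conditional becomes sharply peaked); for extreme counts the
  Gaussian mode on standardised richness is preferable.
- Dense Cholesky updates of the spatial field scale as O(n³) per
  iteration and are intended for grids up to a few thousand cells.
- wAIC uses the conditional (latent-field) likelihood; marginal-
  likelihood versions would penalise the spatial field differently.
- The half-open cell convention means a fire centroid exactly on the
  grid's south or east boundary falls outside every cell; delineation
  keeps such fires but the cell assignment is −1 and they drop out of
  cell summaries.
- CVs of attribute distributions are sensitive to the raw-scale
  re-expression choice documented above.
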