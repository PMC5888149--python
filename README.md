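# pyrodiv

Pyrodiversity — the variability of a landscape's fire regime across fire
size, season, return interval and intensity — has been proposed as a
driver of biodiversity in flammable ecosystems, and savanna management
(patch mosaic burning) often assumes it. `pyrodiv` is a desk-scale
implementation of a continent-wide analysis pipeline for testing
this hypothesis on African savanna birds and mammals: it delineates
individual fires from satellite-style burn-date rasters, computes a
per-grid-cell pyrodiversity index, and fits Bayesian spatial models of
species richness in which the fire effects are allowed to differ
between wet (> 650 mm yr⁻¹) and dry savannas. It is aimed at fire
ecologists and spatial modellers who want the full method exercisable —
and testable against known ground truth — without continental MODIS /
CRU / IUCN / WDPA downloads: a bundled synthetic-landscape generator
emulates every raw input.

## The method

**Fire events.** A spatiotemporal flood fill groups burned
pixel-observations into individual fires: two observations belong to
the same fire iff they are linked by a chain of spatially adjacent
observations (8-neighbour by default) whose burn dates differ by at
most 8 days per link. Each fire gets four attributes: `logArea`
(ln km²), `fireday` (signed days between ignition and the 15th of the
locally wettest month), `logFRI` (ln mean days since each pixel's
previous burn) and `logFRP` (ln mean radiative power, MW, of the
active-fire detections matched to the footprint). Fires lacking an FRI
or FRP record are excluded.

**Pyrodiversity index.** After dividing each attribute by its standard
deviation over the whole fire set, every fire is a point in 4-D
attribute space, and the pyrodiversity of a half-degree cell is the
volume of the minimum convex hull of its fires' points, bias-corrected
for sample size with a nonparametric bootstrap:

    V̂ = max(0, 2·V_obs − mean_b V_b),   V_b = hull volume of resample b.

**Richness models.** Per-cell richness counts y_i follow

    y_i ~ Poisson(exp(η_i)),
    η_i = x_iᵀβ + φ_i + ε_i,

where x_i contains an intercept, a cubic B-spline of standardised NPP
with two interior knots, linear topographic heterogeneity (SD of
elevation), a wet-savanna indicator, and wet- and dry-stratum slopes for
each fire covariate (pyrodiversity plus either the four attribute means
or the four attribute CVs — never both, they are collinear). φ is an
intrinsic CAR (Besag) spatial field on queen adjacency, ε is iid
overdispersion; both precisions carry Gamma(0.1, 0.5) priors. Inference
is by blocked-Gibbs MCMC with split-R̂ convergence monitoring; models
(e.g. linear vs quadratic fire effects) are compared by wAIC, and an
effect is "supported" when its 95 % credible interval excludes zero.

**Protected-area contrasts.** Cells inside each protected area (≥ 50 %
coverage) are compared with cells in its 100-km buffer ring (≥ 20 % of
cell area in the ring) by Gaussian random-intercept models,
metric ~ status + (1 | PA), fitted by profile REML.

## Worked example

```python
import pyrodiv as pv
from pyrodiv.grids import GridSpec

res = pv.run_pipeline(
    seed=7,
    grid=GridSpec(n_rows=14, n_cols=14),
    years=8, n_pa=5,
    truth=pv.SyntheticTruth(beta_pyro_wet=0.09, beta_pyro_dry=0.03),
    mcmc=dict(chains=2, iterations=2000, burn_in=1000),
    pa_threshold=0.0,
)
print(f"fires delineated: {len(res['fires'])}")
print(res["results"].summary())
```

prints

```
fires delineated: 3746
Intrinsic-CAR richness model (poisson, n=193, draws=2000)
converged: True   wAIC: 1035.3
             coef  median   q025   q975  supported   rhat
        intercept   1.934  1.408  2.405       True  1.011
     npp_spline_1  -0.138 -0.887  0.691      False  1.002
     npp_spline_2   0.448 -0.041  1.016      False  1.016
     npp_spline_3   0.950  0.129  1.826       True  1.000
     npp_spline_4   0.582 -0.061  1.248      False  1.005
     npp_spline_5   0.765  0.028  1.534       True  1.007
         topo_het   0.037 -0.024  0.104      False  1.048
              wet  -0.076 -0.341  0.206      False  1.004
pyrodiversity:wet   0.067 -0.042  0.188      False  1.016
pyrodiversity:dry   0.011 -0.074  0.096      False  1.006
```

The landscape was simulated with a true wet-stratum pyrodiversity
effect of 0.09 and a dry-stratum effect of 0.03 (log-richness per SD of
pyrodiversity): the posterior medians (0.067 wet, 0.011 dry) recover
the ordering, and both 95 % intervals cover their truth — a single
replicate on a 14 × 14 landscape carries limited information, which is
why the validation studies below aggregate over many replicates.
`res["contrast"]` holds the protected-area mixed-model table
(β ± SE per fire metric), and `res["results"].predicted_richness_curve`
gives richness–pyrodiversity response curves with credible bands.

The same stages are available from the shell:

```bash
pyrodiv simulate --seed 1 --out data/
pyrodiv fires    --data data/ --out fires.csv
pyrodiv index    --fires fires.csv --data data/ --seed 1 --out cells_fire.csv
pyrodiv grid     --data data/ --cells-fire cells_fire.csv --out cells.csv
pyrodiv fit      --cells cells.csv --data data/ --group mammals_all --out fit/
pyrodiv contrast --cells cells.csv --data data/ --out contrast.csv
```

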