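"""Simulation studies used for validation and reproduction of results.

These are the package's canonical numerical experiments: Monte-Carlo
verification of the hull-volume geometry, the bootstrap bias-reduction
study, parameter-recovery and model-selection studies for the CAR
richness model, and the protected-area GLMM recovery study. Each is a
pure function of its seed, so the studies are exactly reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .car_model import RichnessCARModel
from .covariates import build_cell_table
from .fire_events import BurnHistory, fires_from_rasters
from .grids import GridSpec
from .pa_contrast import RandomInterceptModel, fit_random_intercept
from .pyrodiversity import bootstrap_corrected_volume, cell_summaries, hull_volume
from .synthetic import (
    SyntheticTruth,
    default_fire_regime,
    gen_environment,
    gen_fire_history,
    gen_richness,
)


def mc_hull_volume(points: np.ndarray, n_draws: int = 1_000_000,
                   seed: int = 0, chunk: int = 200_000) -> float:
    """Hit-or-miss Monte-Carlo estimate of a point cloud's hull volume.

    Membership is tested by Delaunay tessellation location (independent
    of the facet-based volume computation), with draws uniform on the
    cloud's bounding box; the estimate is the hit fraction times the box
    volume. Draws are processed in chunks to bound memory.
    """
    pts = np.asarray(points, float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    tri = Delaunay(pts)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        u = lo + rng.random((m, pts.shape[1])) * (hi - lo)
        hits += int((tri.find_simplex(u) >= 0).sum())
        done += m
    return box_vol * hits / n_draws


def bootstrap_bias_study(sizes=(20, 50, 100), n_reps: int = 100, B: int = 200,
                         seed: int = 0) -> pd.DataFrame:
    """Raw vs bootstrap-corrected hull volume error for uniform hypercubes.

    True volume is 1; reports the mean absolute error of both estimators
    at each sample size.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        raw_err, cor_err = [], []
        for _ in range(n_reps):
            pts = rng.random((n, 4))
            v = hull_volume(pts)
            c = bootstrap_corrected_volume(pts, B=B, seed=int(rng.integers(2**31)))
            raw_err.append(abs(v - 1.0))
            cor_err.append(abs(c - 1.0))
        rows.append({"n": n, "mean_abs_err_raw": float(np.mean(raw_err)),
                     "mean_abs_err_corrected": float(np.mean(cor_err))})
    return pd.DataFrame(rows)


def recovery_replicate(
    rep_seed: int,
    beta_pyro_wet: float = 0.09,
    beta_pyro_dry: float = 0.03,
    grid: GridSpec | None = None,
    years: int = 8,
    n_min: int = 10,
    B: int = 100,
    mcmc: dict | None = None,
) -> dict:
    """One full recovery run: simulate fires, compute pyrodiversity,
    generate richness under known wet/dry effects, refit, and report the
    wet/dry posterior summaries with coverage of the truth."""
    grid = grid or GridSpec()
    ss = np.random.SeedSequence(rep_seed)
    s = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]
    env = gen_environment(grid, s[0])
    regime = default_fire_regime(env)
    burn, det, _ = gen_fire_history(env, regime, years, s[1])
    fires = fires_from_rasters(BurnHistory(burn, grid), det, env.peak_rain_month)
    summary = cell_summaries(fires, grid, n_min=n_min, B=B, seed=s[2])
    truth = SyntheticTruth(beta_pyro_wet=beta_pyro_wet, beta_pyro_dry=beta_pyro_dry)
    rich = gen_richness(env, summary["pyrodiversity"].to_numpy(), truth, s[3])
    cells = build_cell_table(env, cell_fire_summary=summary,
                             richness_direct=rich, pa_threshold=0.0)
    model = RichnessCARModel.from_cells(cells, "mammals_all", grid,
                                        fire_covariates=("pyrodiversity",))
    mcmc = mcmc or dict(chains=2, iterations=1600, burn_in=700)
    res = model.fit(seed=s[4], **mcmc)
    tbl = res.coef_table().set_index("coef")
    w, d = tbl.loc["pyrodiversity:wet"], tbl.loc["pyrodiversity:dry"]
    return {
        "wet_median": float(w["median"]), "wet_lo": float(w["q025"]),
        "wet_hi": float(w["q975"]),
        "dry_median": float(d["median"]), "dry_lo": float(d["q025"]),
        "dry_hi": float(d["q975"]),
        "wet_covered": bool(w["q025"] <= beta_pyro_wet <= w["q975"]),
        "dry_covered": bool(d["q025"] <= beta_pyro_dry <= d["q975"]),
        "wet_exceeds_dry": bool(w["median"] > d["median"]),
    }


def _direct_pyro_cells(grid: GridSpec, env, truth: SyntheticTruth, seed: int):
    """Cell table with a direct (fire-free) pyrodiversity surface."""
    rng = np.random.default_rng(seed)
    pyro = 20.0 - 0.01 * env.map_mm + rng.normal(0, 2.5, grid.n_cells)
    rich = gen_richness(env, pyro, truth, seed + 1)
    cells = build_cell_table(env, richness_direct=rich, pa_threshold=0.0)
    cells["pyrodiversity"] = pyro
    return cells


def selection_replicate(rep_seed: int, quadratic_truth: bool,
                        grid: GridSpec | None = None,
                        mcmc: dict | None = None) -> bool:
    """Fit linear and quadratic pyrodiversity models to one simulated
    dataset; True when the quadratic model has the lower wAIC."""
    grid = grid or GridSpec(n_rows=12, n_cols=12)
    env = gen_environment(grid, rep_seed)
    if quadratic_truth:
        truth = SyntheticTruth(beta_pyro_wet=0.10, beta_pyro_dry=0.05,
                               beta_pyro2_wet=-0.10, beta_pyro2_dry=-0.10)
    else:
        truth = SyntheticTruth(beta_pyro_wet=0.10, beta_pyro_dry=0.05)
    cells = _direct_pyro_cells(grid, env, truth, 7000 + rep_seed)
    mcmc = mcmc or dict(chains=2, iterations=1000, burn_in=500)
    waics = {}
    for quad in (False, True):
        m = RichnessCARModel.from_cells(cells, "mammals_all", grid,
                                        fire_covariates=("pyrodiversity",),
                                        quadratic=quad)
        waics[quad] = m.fit(seed=9000 + rep_seed, **mcmc).waic()
    return waics[True] < waics[False]


def glmm_recovery_study(n_reps: int = 50, beta: float = -0.3,
                        sigma_pa: float = 0.5, sigma_e: float = 0.4,
                        n_pa: int = 12, n_in: int = 6, n_out: int = 8,
                        seed: int = 0) -> dict:
    """Random-intercept recovery: mean estimate vs truth over replicates,
    plus the profile-REML vs grid-search deviance gap on the last fit."""
    betas, sigmas = [], []
    gap = None
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        ys, st, gid = [], [], []
        for p in range(n_pa):
            b = rng.normal(0, sigma_pa)
            for _ in range(n_in):
                ys.append(1.0 + b + beta + rng.normal(0, sigma_e))
                st.append(1.0); gid.append(p)
            for _ in range(n_out):
                ys.append(1.0 + b + rng.normal(0, sigma_e))
                st.append(0.0); gid.append(p)
        model = RandomInterceptModel(np.array(ys), np.array(st), np.array(gid))
        res = model.fit()
        betas.append(res.beta_status)
        sigmas.append(np.sqrt(res.sigma2_group))
        if r == n_reps - 1:
            lams = np.concatenate([[0.0], np.exp(np.linspace(-12, 8, 2001))])
            gap = res.reml_deviance - min(model.reml_deviance(l) for l in lams)
    betas = np.array(betas)
    return {
        "beta_mean": float(betas.mean()),
        "beta_mc_se": float(betas.std(ddof=1) / np.sqrt(n_reps)),
        "sigma_pa_mean": float(np.mean(sigmas)),
        "deviance_gap_vs_grid": float(gap),
        "truth_beta": beta,
        "truth_sigma_pa": sigma_pa,
    }
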