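"""End-to-end pipeline: simulate → fires → index → grid → fit → contrast.

A convenience wrapper used by the CLI, the acceptance checks and the
reproducibility tests. Every stage is seeded from one master seed via
`numpy.random.SeedSequence`, so a full run is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .car_model import RichnessCARModel, effects_table
from .covariates import build_cell_table
from .fire_events import BurnHistory, fires_from_rasters
from .grids import GridSpec
from .pa_contrast import build_buffer_table, contrast_report
from .pyrodiversity import cell_summaries
from .synthetic import (
    SyntheticTruth,
    default_fire_regime,
    gen_environment,
    gen_fire_history,
    gen_protected_areas,
    gen_richness,
)


def run_pipeline(
    seed: int,
    grid: GridSpec | None = None,
    years: int = 8,
    n_pa: int = 6,
    truth: SyntheticTruth | None = None,
    n_min: int = 10,
    B: int = 100,
    response: str = "birds_all",
    fire_covariates: tuple = ("pyrodiversity",),
    mcmc: dict | None = None,
    buffer_km: float = 100.0,
    inclusion_frac: float = 0.2,
    fit_model: bool = True,
    pa_threshold: float = 0.5,
) -> dict:
    """Run the full analysis on a freshly simulated landscape.

    Returns a dict with the fire table, cell table, model results (when
    `fit_model`), effects table and PA contrast report.
    """
    grid = grid or GridSpec()
    truth = truth or SyntheticTruth(seed=seed)
    ss = np.random.SeedSequence(seed)
    s_env, s_fire, s_rich, s_pa, s_idx, s_fit = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    ]

    env = gen_environment(grid, s_env)
    regime = default_fire_regime(env)
    burn, detections, _ = gen_fire_history(env, regime, years, s_fire)
    history = BurnHistory(burn, grid)
    fires = fires_from_rasters(history, detections, env.peak_rain_month)
    summary = cell_summaries(fires, grid, n_min=n_min, B=B, seed=s_idx)
    pa_polys = gen_protected_areas(env, n_pa, s_pa)
    richness = gen_richness(env, summary["pyrodiversity"].to_numpy(), truth, s_rich)
    cells = build_cell_table(env, cell_fire_summary=summary, pa_polys=pa_polys,
                             richness_direct=richness, pa_threshold=pa_threshold)

    out = {"env": env, "fires": fires, "cells": cells, "truth": truth,
           "pa_polys": pa_polys}
    if fit_model:
        model = RichnessCARModel.from_cells(
            cells, response, grid, fire_covariates=fire_covariates)
        res = model.fit(seed=s_fit, **(mcmc or {}))
        out["results"] = res
        out["effects"] = effects_table({response: res})
        out["waic"] = res.waic()
    buffer_tbl = build_buffer_table(cells, pa_polys, grid, buffer_km, inclusion_frac)
    out["buffer_table"] = buffer_tbl
    out["contrast"] = contrast_report(buffer_tbl)
    return out
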