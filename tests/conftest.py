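import numpy as np
import pandas as pd
import pytest

import pyrodiv as pv


@pytest.fixture(scope="session")
def small_grid():
    return pv.GridSpec(n_rows=10, n_cols=10)


@pytest.fixture(scope="session")
def env(small_grid):
    return pv.gen_environment(small_grid, seed=1)


@pytest.fixture(scope="session")
def fire_stage(env, small_grid):
    """Delineated fire table plus the raw history, shared across tests."""
    regime = pv.default_fire_regime(env)
    burn, detections, truth_fires = pv.gen_fire_history(env, regime, years=6, seed=2)
    history = pv.BurnHistory(burn, small_grid)
    table = pv.fires_from_rasters(history, detections, env.peak_rain_month)
    return {
        "history": history,
        "detections": detections,
        "truth_fires": truth_fires,
        "table": table,
    }


def random_burn_history(rng, grid, n_layers=2, burn_prob=0.25, date_span=40):
    """Small random burn raster for oracle comparisons."""
    H, W = grid.pixel_rows, grid.pixel_cols
    layers = np.full((n_layers, H, W), -1, dtype=np.int32)
    for k in range(n_layers):
        mask = rng.random((H, W)) < burn_prob
        dates = rng.integers(k * 400, k * 400 + date_span, size=(H, W))
        layers[k][mask] = dates[mask]
    return pv.BurnHistory(layers, grid)


def make_model_cells(grid, env, truth, seed, pyro_noise=2.5):
    """Cell table with a direct synthetic pyrodiversity surface.

    Used by model-focused tests that do not need the fire simulation:
    pyrodiversity declines with rainfall plus noise, and richness is
    drawn from the generator with the given truth.
    """
    rng = np.random.default_rng(seed)
    pyro = 20.0 - 0.01 * env.map_mm + rng.normal(0, pyro_noise, grid.n_cells)
    rich = pv.gen_richness(env, pyro, truth, seed + 1)
    cells = pv.build_cell_table(env, richness_direct=rich, pa_threshold=0.0)
    cells["pyrodiversity"] = pyro
    return cells
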