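"""Synthetic savanna landscapes with known ground truth.

Generates every input the pipeline consumes — rainfall climatology,
elevation, annual NPP, multi-year burn-date rasters with active-fire
detections, protected-area polygons, species ranges with traits, and
per-cell richness counts drawn from the same model family the inference
module fits — so each downstream stage can be tested against a recorded
truth without any external data.

The default regime encodes the qualitative structure of African savanna
fire ecology: fires concentrated in the dry season; lognormal fire sizes
and radiative powers; fire frequency rising with rainfall; and fire
*variability* (season spread, size spread, intensity spread) declining
with rainfall, so that the pyrodiversity index computed downstream is
highest in dry savannas and declines above the 650 mm wet/dry threshold.
Richness increases with NPP and the pyrodiversity effect is stronger in
wet savannas.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import box, mapping, shape

from .grids import GridSpec, fifteenth_of_month, day_to_date

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365  # calendar convenience only; dates stay integer days


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentStack:
    """Bundled environmental surfaces sharing one grid geometry.

    monthly_rain : (n_cells, 12) mm per month (long-term means)
    elevation    : (pixel_rows, pixel_cols) metres
    npp_annual   : (n_years, pixel_rows, pixel_cols) kg C m⁻² yr⁻¹
    """

    grid: GridSpec
    monthly_rain: np.ndarray
    elevation: np.ndarray
    npp_annual: np.ndarray

    @property
    def map_mm(self) -> np.ndarray:
        """Mean annual precipitation per cell (mm yr⁻¹)."""
        return self.monthly_rain.sum(axis=1)

    @property
    def peak_rain_month(self) -> np.ndarray:
        """Wettest calendar month (1–12) per cell; earliest wins ties."""
        return self.monthly_rain.argmax(axis=1) + 1


@dataclass
class FireRegimeParams:
    """Per-cell fire-regime parameters.

    fires_per_yr     : expected ignitions per cell per year
    size_mu, size_sigma : lognormal parameters of fire size in *pixels*
    season_offset_days  : mean ignition day relative to the local rain peak
    season_sd_days      : circular SD of ignition timing (days), in (0, 120]
    frp_mu, frp_sigma   : lognormal parameters of fire radiative power (MW)
    detection_rate      : probability an active burn pixel yields a detection
    spread_days         : max days between ignition and last pixel of a fire
    """

    fires_per_yr: np.ndarray
    size_mu: np.ndarray
    size_sigma: np.ndarray
    season_offset_days: np.ndarray
    season_sd_days: np.ndarray
    frp_mu: np.ndarray
    frp_sigma: np.ndarray
    detection_rate: float = 0.9
    spread_days: int = 6

    def __post_init__(self):
        for name in ("fires_per_yr", "size_sigma", "frp_sigma"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        sd = np.asarray(self.season_sd_days)
        if np.any(sd <= 0) or np.any(sd > 120):
            raise ValueError("season_sd_days must lie in (0, 120]")


@dataclass
class SyntheticTruth:
    """Hidden parameters of the richness-generating process.

    Effects are on the log scale per SD of the (standardised) covariate,
    matching the scale on which the inference module reports them.
    """

    beta0: float = 2.5
    beta_pyro_wet: float = 0.09
    beta_pyro_dry: float = 0.03
    beta_pyro2_wet: float = 0.0
    beta_pyro2_dry: float = 0.0
    beta_topo: float = 0.05
    npp_lin: float = 0.25
    npp_quad: float = -0.08
    attr_betas: dict = field(default_factory=dict)
    overdispersion_sd: float = 0.08
    spatial_sd: float = 0.0
    seed: int = 0

    def to_json(self, path) -> None:
        d = dict(self.__dict__)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape_, sigma):
    """Standardised Gaussian random field via kernel-smoothed white noise."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape_), sigma, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def gen_environment(
    grid: GridSpec,
    seed: int,
    map_range: tuple[float, float] = (300.0, 1400.0),
) -> EnvironmentStack:
    """Generate rainfall, elevation and NPP surfaces.

    MAP spans `map_range` across the grid with smooth spatial structure;
    the wettest month varies spatially; NPP is a monotone function of MAP
    plus noise (rank correlation with MAP > 0 by construction).
    """
    rng = np.random.default_rng(seed)
    H, W = grid.pixel_rows, grid.pixel_cols
    lo, hi = map_range

    # rainfall gradient: large-scale trend + GRF, rescaled to span map_range
    rows = np.linspace(0, 1, H)[:, None] * np.ones((1, W))
    trend = rows  # wetter to the south
    grf = _smooth_field(rng, (H, W), sigma=grid.pixels_per_cell * 2.0)
    raw = trend + 0.35 * grf
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    # skew so the 650 mm wet/dry threshold sits near the median cell
    gamma = np.log((650.0 - lo) / (hi - lo)) / np.log(0.5) if lo < 650.0 < hi else 1.0
    map_pixels = lo + raw**gamma * (hi - lo)

    # cell-level MAP = mean over the cell's pixels
    ppc = grid.pixels_per_cell
    map_cells = map_pixels.reshape(grid.n_rows, ppc, grid.n_cols, ppc).mean(axis=(1, 3))
    map_cells = map_cells.ravel()

    # peak rain month drifts smoothly across the map
    month_field = _smooth_field(rng, (grid.n_rows, grid.n_cols), sigma=3.0)
    peak_month = (np.round(12.5 + 2.5 * month_field).astype(int) - 1) % 12 + 1
    peak_month = peak_month.ravel()

    # monthly climatology: wrapped (von Mises) profile around the peak month
    months = np.arange(1, 13)
    kappa = 2.0
    ang = 2 * np.pi * (months[None, :] - peak_month[:, None]) / 12.0
    w = np.exp(kappa * np.cos(ang))
    monthly = w / w.sum(axis=1, keepdims=True) * map_cells[:, None]

    elevation = 800.0 + 250.0 * _smooth_field(rng, (H, W), sigma=grid.pixels_per_cell * 1.5) \
        + 40.0 * rng.standard_normal((H, W))

    # NPP ~ saturating monotone function of MAP, with interannual noise
    n_years = 5
    base = 1.2 * (1.0 - np.exp(-map_pixels / 900.0))  # kg C m^-2 yr^-1
    npp = np.empty((n_years, H, W))
    for y in range(n_years):
        noise = 1.0 + 0.10 * _smooth_field(rng, (H, W), sigma=grid.pixels_per_cell) \
            + 0.05 * rng.standard_normal((H, W))
        npp[y] = np.clip(base * noise, 0.0, None)

    return EnvironmentStack(grid, monthly, elevation, npp)


# ---------------------------------------------------------------------------
# fire regime and fire history
# ---------------------------------------------------------------------------

def default_fire_regime(env: EnvironmentStack, detection_rate: float = 0.9) -> FireRegimeParams:
    """Rainfall-driven regime reproducing the dry>wet pyrodiversity gradient.

    Fire frequency rises with rainfall (more fuel), while the spreads of
    season, size and intensity shrink, so the 4D attribute hull — the
    pyrodiversity index — is largest in dry cells.
    """
    m = env.map_mm
    wetness = np.clip((m - 300.0) / 1100.0, 0.0, 1.0)  # 0 dry .. 1 wet
    return FireRegimeParams(
        fires_per_yr=3.0 + 3.0 * wetness,
        size_mu=np.log(5.0) * np.ones_like(m),
        size_sigma=1.3 - 0.9 * wetness,
        season_offset_days=150.0 * np.ones_like(m),
        season_sd_days=np.clip(95.0 - 75.0 * wetness, 15.0, 120.0),
        frp_mu=np.log(30.0) + 0.5 * wetness,
        frp_sigma=1.2 - 0.8 * wetness,
        detection_rate=detection_rate,
    )


def _grow_fire(rng, grid, occupied, ign, n_pixels, spread_days):
    """Stochastic region-growing from an ignition pixel.

    Returns (pixels, steps): lists of (row, col) and the graph distance of
    each pixel from the ignition. Growth uses 4-connectivity and avoids
    pixels already burned in the same year layer.
    """
    H, W = grid.pixel_rows, grid.pixel_cols
    pixels = [ign]
    step = {ign: 0}
    frontier = [ign]
    while len(pixels) < n_pixels and frontier:
        i = rng.integers(len(frontier))
        r, c = frontier[i]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
            if 0 <= r + dr < H and 0 <= c + dc < W
            and (r + dr, c + dc) not in step
            and not occupied[r + dr, c + dc]
        ]
        if not nbrs:
            frontier.pop(i)
            continue
        nxt = nbrs[rng.integers(len(nbrs))]
        step[nxt] = step[(r, c)] + 1
        pixels.append(nxt)
        frontier.append(nxt)
    steps = [step[p] for p in pixels]
    return pixels, steps


def gen_fire_history(
    env: EnvironmentStack,
    regime: FireRegimeParams,
    years: int,
    seed: int,
):
    """Simulate multi-year burn rasters and active-fire detections.

    Returns
    -------
    burn_layers : (years, pixel_rows, pixel_cols) int32
        Per-pixel burn date (days since epoch), −1 where unburned. Each
        layer holds at most one burn per pixel; a fire cannot re-burn a
        pixel already burned in the same layer.
    detections : DataFrame [lon, lat, date, frp_mw]
        Point detections thinned by the regime's detection rate.
    fires_truth : DataFrame [fire_id, ignition_date, n_pixels, cell_id]
        The generator's own record of every simulated fire.
    """
    if years < 2:
        raise ValueError("need years >= 2: fire-return intervals require a prior burn")
    rng = np.random.default_rng(seed)
    grid = env.grid
    H, W = grid.pixel_rows, grid.pixel_cols
    burn = np.full((years, H, W), -1, dtype=np.int32)
    peak = env.peak_rain_month
    ppc = grid.pixels_per_cell

    det_rows = []
    truth_rows = []
    fid = 0
    for year in range(years):
        occupied = np.zeros((H, W), bool)
        n_fires_cell = rng.poisson(np.asarray(regime.fires_per_yr, float))
        for cid in np.flatnonzero(n_fires_cell):
            crow, ccol = grid.cell_rowcol(cid)
            for _ in range(n_fires_cell[cid]):
                # ignition timing: wrapped normal around (rain peak + offset)
                anchor = fifteenth_of_month(2000 + year, int(peak[cid]))
                offset = float(np.atleast_1d(regime.season_offset_days)[
                    min(cid, np.size(regime.season_offset_days) - 1)])
                sd = float(np.atleast_1d(regime.season_sd_days)[
                    min(cid, np.size(regime.season_sd_days) - 1)])
                # layers partition the record by ignition year only; the
                # date itself may spill past the calendar year boundary
                date = int(round(anchor + offset + rng.normal(0.0, sd)))

                mu = float(np.atleast_1d(regime.size_mu)[min(cid, np.size(regime.size_mu) - 1)])
                sig = float(np.atleast_1d(regime.size_sigma)[min(cid, np.size(regime.size_sigma) - 1)])
                n_pix = max(1, int(round(rng.lognormal(mu, sig))))

                ir = crow * ppc + rng.integers(ppc)
                ic = ccol * ppc + rng.integers(ppc)
                if occupied[ir, ic]:
                    continue
                pixels, steps = _grow_fire(rng, grid, occupied, (ir, ic), n_pix, regime.spread_days)
                max_step = max(max(steps), 1)
                fmu = float(np.atleast_1d(regime.frp_mu)[min(cid, np.size(regime.frp_mu) - 1)])
                fsig = float(np.atleast_1d(regime.frp_sigma)[min(cid, np.size(regime.frp_sigma) - 1)])
                for (r, c), s in zip(pixels, steps):
                    pdate = date + int(round(s / max_step * regime.spread_days))
                    burn[year, r, c] = pdate
                    occupied[r, c] = True
                    if rng.random() < regime.detection_rate:
                        lon, lat = grid.pixel_center_lonlat(r, c)
                        det_rows.append((float(lon), float(lat), pdate,
                                         float(rng.lognormal(fmu, fsig))))
                truth_rows.append((fid, date, len(pixels), cid))
                fid += 1

    detections = pd.DataFrame(det_rows, columns=["lon", "lat", "date", "frp_mw"])
    fires_truth = pd.DataFrame(
        truth_rows, columns=["fire_id", "ignition_date", "n_pixels", "cell_id"]
    )
    return burn, detections, fires_truth


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

def _zscore(x):
    x = np.asarray(x, float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def gen_richness(
    env: EnvironmentStack,
    cell_pyrodiversity: np.ndarray,
    truth: SyntheticTruth,
    seed: int,
    groups: tuple[str, ...] = ("mammals_all", "birds_all"),
    group_offsets: dict | None = None,
) -> pd.DataFrame:
    """Draw per-cell richness counts from the fitted-model family.

    Poisson-lognormal with a log link: the linear predictor combines an
    NPP response (quadratic in standardised NPP, a stand-in for the
    smooth productivity–richness curve), a linear topographic effect, a
    wet/dry-specific pyrodiversity effect (optionally quadratic), iid
    overdispersion and an optional smooth spatial field.
    """
    rng = np.random.default_rng(seed)
    grid = env.grid
    ppc = grid.pixels_per_cell
    npp_cells = env.npp_annual.mean(axis=0).reshape(
        grid.n_rows, ppc, grid.n_cols, ppc).mean(axis=(1, 3)).ravel()
    topo_cells = env.elevation.reshape(
        grid.n_rows, ppc, grid.n_cols, ppc).std(axis=(1, 3)).ravel()

    pyro = np.asarray(cell_pyrodiversity, float)
    fin = np.isfinite(pyro)
    if not fin.any():
        raise ValueError("cell_pyrodiversity has no finite values")
    mu, sd = pyro[fin].mean(), pyro[fin].std()
    sd = sd if sd > 0 else 1.0
    # standardise on the observed cells; unobserved cells sit at the mean,
    # matching the scale on which the model reports effects
    pyro_z = np.where(fin, (pyro - mu) / sd, 0.0)
    npp_z = _zscore(npp_cells)
    topo_z = _zscore(topo_cells)
    wet = env.map_mm > 650.0

    eta = (
        truth.npp_lin * npp_z
        + truth.npp_quad * npp_z**2
        + truth.beta_topo * topo_z
        + np.where(wet, truth.beta_pyro_wet, truth.beta_pyro_dry) * pyro_z
        + np.where(wet, truth.beta_pyro2_wet, truth.beta_pyro2_dry) * pyro_z**2
    )
    if truth.spatial_sd > 0:
        fld = _smooth_field(rng, (grid.n_rows, grid.n_cols), sigma=2.0).ravel()
        eta = eta + truth.spatial_sd * fld

    offsets = group_offsets or {}
    out = {"cell_id": np.arange(grid.n_cells)}
    for g in groups:
        b0 = truth.beta0 + offsets.get(g, 0.0)
        lin = b0 + eta + rng.normal(0.0, truth.overdispersion_sd, grid.n_cells)
        if np.any(lin > 20.0):
            raise ValueError("linear predictor exceeds exp(20): mis-parameterised truth")
        out[g] = rng.poisson(np.exp(lin))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# species ranges and traits
# ---------------------------------------------------------------------------

def gen_species_ranges(
    env: EnvironmentStack,
    richness_target: np.ndarray,
    seed: int,
    n_species: int = 400,
    bat_fraction: float = 0.2,
):
    """Place rectangular species ranges so overlap tracks a target surface.

    Range centres are drawn by systematic (low-variance) sampling from a
    distribution proportional to the sharpened target richness, so cells
    with high target richness accumulate more overlapping ranges
    (Spearman ρ with the target > 0.8 at defaults). Returns (list of
    shapely polygons, traits DataFrame).
    """
    rng = np.random.default_rng(seed)
    grid = env.grid
    tgt = np.asarray(richness_target, float)
    tgt = np.clip(tgt, 0, None)
    if n_species == 0:
        return [], pd.DataFrame(columns=["species_id", "body_mass_kg", "is_bat"])
    p = tgt**4
    p = np.ones_like(tgt) / len(tgt) if p.sum() == 0 else p / p.sum()
    cdf = np.cumsum(p)
    u = (np.arange(n_species) + rng.random(n_species)) / n_species
    cids = np.searchsorted(cdf, np.clip(u, 0, cdf[-1] - 1e-12))

    centers = grid.cell_centers()
    polys = []
    is_bat = rng.random(n_species) < bat_fraction
    mass = np.where(
        is_bat,
        rng.lognormal(np.log(0.02), 0.8, n_species),
        rng.lognormal(np.log(1.0), 1.5, n_species),
    )
    for s in range(n_species):
        lon, lat = centers[cids[s]]
        hw = rng.uniform(0.7, 2.2) * grid.cell_size_deg  # half-width, deg
        hh = rng.uniform(0.7, 2.2) * grid.cell_size_deg
        polys.append(box(lon - hw, lat - hh, lon + hw, lat + hh))
    traits = pd.DataFrame(
        {"species_id": np.arange(n_species), "body_mass_kg": mass, "is_bat": is_bat}
    )
    return polys, traits


# ---------------------------------------------------------------------------
# protected areas
# ---------------------------------------------------------------------------

def gen_protected_areas(env: EnvironmentStack, n_pa: int, seed: int):
    """Pack `n_pa` disjoint rectangular protected areas onto the grid.

    Each PA spans at least 2×2 cells (so it fully covers at least one
    cell); combined coverage stays below half the grid. If the requested
    count cannot be packed, fewer are returned with a logged warning.
    Returns a list of (pa_id, polygon).
    """
    rng = np.random.default_rng(seed)
    grid = env.grid
    pas = []
    covered = 0.0
    total = grid.n_rows * grid.n_cols * grid.cell_size_deg**2
    attempts = 0
    while len(pas) < n_pa and attempts < 200 * max(n_pa, 1):
        attempts += 1
        w_cells = rng.integers(2, 5)
        h_cells = rng.integers(2, 5)
        col = rng.integers(0, max(grid.n_cols - w_cells, 1))
        row = rng.integers(0, max(grid.n_rows - h_cells, 1))
        west = grid.origin_lon + col * grid.cell_size_deg
        north = grid.origin_lat - row * grid.cell_size_deg
        poly = box(west, north - h_cells * grid.cell_size_deg,
                   west + w_cells * grid.cell_size_deg, north)
        if any(poly.intersects(p) for _, p in pas):
            continue
        if covered + poly.area > 0.5 * total:
            continue
        pas.append((len(pas), poly))
        covered += poly.area
    if len(pas) < n_pa:
        warnings.warn(
            f"packed only {len(pas)} of {n_pa} requested protected areas",
            stacklevel=2,
        )
        logger.warning("packed only %d of %d protected areas", len(pas), n_pa)
    return pas


# ---------------------------------------------------------------------------
# file writers / readers (lossless round trip)
# ---------------------------------------------------------------------------

def write_dataset(outdir, env, burn_layers=None, detections=None,
                  pa_polys=None, range_polys=None, traits=None, truth=None):
    """Write a generated dataset to plain-text files under `outdir`."""
    import os

    from .grids import write_ascii_raster

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "grid.json"), "w") as fh:
        json.dump(env.grid.to_dict(), fh, indent=1)
    pd.DataFrame(
        env.monthly_rain, columns=[f"m{i:02d}" for i in range(1, 13)]
    ).to_csv(os.path.join(outdir, "monthly_rain.csv"), index_label="cell_id")
    write_ascii_raster(os.path.join(outdir, "elevation.asc"), env.elevation, env.grid,
                       nodata=-9999)
    for y in range(env.npp_annual.shape[0]):
        write_ascii_raster(os.path.join(outdir, f"npp_{y}.asc"), env.npp_annual[y],
                           env.grid, nodata=-9999)
    if burn_layers is not None:
        for y in range(burn_layers.shape[0]):
            write_ascii_raster(os.path.join(outdir, f"burn_{y}.asc"),
                               burn_layers[y], env.grid)
    if detections is not None:
        detections.to_csv(os.path.join(outdir, "detections.csv"), index=False)
    if pa_polys is not None:
        _write_geojson(os.path.join(outdir, "protected_areas.geojson"),
                       [(str(i), p) for i, p in pa_polys])
    if range_polys is not None:
        _write_geojson(os.path.join(outdir, "ranges.geojson"),
                       [(str(i), p) for i, p in enumerate(range_polys)])
    if traits is not None:
        traits.to_csv(os.path.join(outdir, "traits.csv"), index=False)
    if truth is not None:
        truth.to_json(os.path.join(outdir, "truth.json"))


def read_dataset(outdir):
    """Read a dataset written by :func:`write_dataset`; returns a dict."""
    import glob
    import os

    from .grids import read_ascii_raster

    with open(os.path.join(outdir, "grid.json")) as fh:
        grid = GridSpec.from_dict(json.load(fh))
    rain = pd.read_csv(os.path.join(outdir, "monthly_rain.csv"), index_col=0).to_numpy()
    elev, _ = read_ascii_raster(os.path.join(outdir, "elevation.asc"))
    npp_files = sorted(glob.glob(os.path.join(outdir, "npp_*.asc")))
    npp = np.stack([read_ascii_raster(f)[0] for f in npp_files]).astype(float)
    env = EnvironmentStack(grid, rain, elev.astype(float), npp)
    out = {"env": env}
    burn_files = sorted(glob.glob(os.path.join(outdir, "burn_*.asc")))
    if burn_files:
        out["burn_layers"] = np.stack(
            [read_ascii_raster(f)[0] for f in burn_files]).astype(np.int32)
    det = os.path.join(outdir, "detections.csv")
    if os.path.exists(det):
        out["detections"] = pd.read_csv(det)
    pa = os.path.join(outdir, "protected_areas.geojson")
    if os.path.exists(pa):
        out["pa_polys"] = [(int(i), p) for i, p in _read_geojson(pa)]
    rg = os.path.join(outdir, "ranges.geojson")
    if os.path.exists(rg):
        out["range_polys"] = [p for _, p in _read_geojson(rg)]
    tr = os.path.join(outdir, "traits.csv")
    if os.path.exists(tr):
        out["traits"] = pd.read_csv(tr)
    tj = os.path.join(outdir, "truth.json")
    if os.path.exists(tj):
        out["truth"] = SyntheticTruth.from_json(tj)
    return out


def _write_geojson(path, named_polys):
    feats = [
        {"type": "Feature", "properties": {"id": pid}, "geometry": mapping(poly)}
        for pid, poly in named_polys
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _read_geojson(path):
    with open(path) as fh:
        gj = json.load(fh)
    return [(f["properties"]["id"], shape(f["geometry"])) for f in gj["features"]]
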