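"""Per-cell analysis table: climate, NPP, topography, protected areas,
species richness partitions.

The analysis unit is the grid cell (quarter-degree style). A cell enters
the richness analysis when it is savanna (MAP ≥ 300 mm yr⁻¹) and at
least half covered by protected area — richness data are most reliable,
and fire regimes least confounded by land use, inside protected areas.
Cells above 650 mm yr⁻¹ are "wet" savanna, below are "dry"; that is the
rainfall threshold at which fire starts to control woody structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grids import GridSpec
from .synthetic import EnvironmentStack

logger = logging.getLogger(__name__)

WET_DRY_THRESHOLD_MM = 650.0
SAVANNA_MIN_RAIN_MM = 300.0
PA_COVERAGE_THRESHOLD = 0.5


def summarise_climate(monthly_rain_12: np.ndarray) -> tuple[float, int]:
    """(MAP, peak month 1–12) from a 12-vector of monthly means.

    MAP is the sum of monthly means; the peak month is the argmax with
    the earliest month winning ties.
    """
    m = np.asarray(monthly_rain_12, float)
    if m.shape != (12,):
        raise ValueError("monthly rain must be a 12-vector")
    return float(m.sum()), int(m.argmax()) + 1


def _cell_block(pixel_raster: np.ndarray, grid: GridSpec, cell_id: int) -> np.ndarray:
    row, col = grid.cell_rowcol(cell_id)
    p = grid.pixels_per_cell
    return pixel_raster[..., row * p:(row + 1) * p, col * p:(col + 1) * p]


def mean_npp(npp_annual: np.ndarray, grid: GridSpec, cell_id: int) -> float:
    """Mean NPP over years then pixels within the cell (kg C m⁻² yr⁻¹).

    With complete data the two averaging orders coincide; missing
    (non-finite) pixels are excluded.
    """
    block = _cell_block(np.asarray(npp_annual, float), grid, cell_id)
    return float(np.nanmean(block))


def topo_heterogeneity(elevation: np.ndarray, grid: GridSpec, cell_id: int) -> float:
    """SD of pixel elevations within the cell (m)."""
    block = _cell_block(np.asarray(elevation, float), grid, cell_id)
    return float(np.nanstd(block))


def pa_coverage(cell_polygon, pa_polygons) -> float:
    """Fraction of the cell's area covered by the union of PA polygons."""
    if not pa_polygons:
        return 0.0
    u = unary_union(list(pa_polygons))
    return float(cell_polygon.intersection(u).area / cell_polygon.area)


def rasterise_richness(range_polygons, grid: GridSpec) -> np.ndarray:
    """Species per cell: count ranges intersecting each cell with area > 0.

    Returns an (n_species, n_cells) boolean presence matrix's column
    sums — i.e. richness — along with nothing else; use
    :func:`presence_matrix` when per-species presence is needed.
    """
    return presence_matrix(range_polygons, grid).sum(axis=0).astype(int)


def presence_matrix(range_polygons, grid: GridSpec) -> np.ndarray:
    """(n_species, n_cells) bool: does each range overlap each cell?"""
    cells = [grid.cell_polygon(c) for c in range(grid.n_cells)]
    out = np.zeros((len(range_polygons), grid.n_cells), bool)
    if not range_polygons:
        return out
    tree = STRtree(cells)
    for s, poly in enumerate(range_polygons):
        for ci in tree.query(poly):
            if poly.intersection(cells[ci]).area > 0:
                out[s, ci] = True
    return out


def partition_species(traits: pd.DataFrame) -> pd.DataFrame:
    """Label species groups from traits.

    Requires columns species_id, body_mass_kg, is_bat, range_size_cells.
    Small = body mass ≤ median (ties inclusive-low), large = complement;
    common = range size ≥ median (ties inclusive-high); bats by flag.
    With all-equal masses the tie rule puts every species in "small".
    """
    t = traits.copy()
    if (t["body_mass_kg"] <= 0).any():
        raise ValueError("body masses must be positive")
    med_mass = t["body_mass_kg"].median()
    med_range = t["range_size_cells"].median()
    t["is_small"] = t["body_mass_kg"] <= med_mass
    t["is_large"] = ~t["is_small"]
    t["is_common"] = t["range_size_cells"] >= med_range
    return t


def _group_richness(presence: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return presence[mask].sum(axis=0).astype(int)


def build_cell_table(
    env: EnvironmentStack,
    cell_fire_summary: pd.DataFrame | None = None,
    pa_polys=None,
    mammal_ranges=None,
    mammal_traits: pd.DataFrame | None = None,
    bird_ranges=None,
    richness_direct: pd.DataFrame | None = None,
    pa_threshold: float = PA_COVERAGE_THRESHOLD,
    savanna_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell analysis table.

    Richness can come from range polygons (rasterised; mammal partitions
    need a traits table) and/or from a directly generated per-cell table
    (columns named per group). Direct columns win on name collisions.
    The in_analysis flag marks savanna cells with PA coverage at or
    above `pa_threshold`.
    """
    grid = env.grid
    n = grid.n_cells
    clim = [summarise_climate(env.monthly_rain[c]) for c in range(n)]
    tbl = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "map_mm": [c[0] for c in clim],
            "peak_rain_month": [c[1] for c in clim],
            "npp": [mean_npp(env.npp_annual, grid, c) for c in range(n)],
            "topo_het": [topo_heterogeneity(env.elevation, grid, c) for c in range(n)],
        }
    )
    tbl["is_wet"] = tbl["map_mm"] > WET_DRY_THRESHOLD_MM
    if savanna_mask is not None:
        tbl["is_savanna"] = np.asarray(savanna_mask, bool).ravel()
    else:
        tbl["is_savanna"] = tbl["map_mm"] >= SAVANNA_MIN_RAIN_MM

    polys = [p for _, p in pa_polys] if pa_polys else []
    tbl["pa_fraction"] = [
        pa_coverage(grid.cell_polygon(c), polys) for c in range(n)
    ]
    tbl["in_analysis"] = tbl["is_savanna"] & (tbl["pa_fraction"] >= pa_threshold)

    if mammal_ranges is not None:
        pres = presence_matrix(mammal_ranges, grid)
        if mammal_traits is not None:
            traits = mammal_traits.copy()
            traits["range_size_cells"] = pres.sum(axis=1)
            traits = traits[traits["range_size_cells"] >= 1].reset_index(drop=True)
            pres = pres[traits.index.to_numpy()] if len(traits) < pres.shape[0] else pres
            traits = partition_species(traits)
            bat = traits["is_bat"].to_numpy(bool)
            tbl["mammals_all"] = pres.sum(axis=0).astype(int)
            tbl["mammals_no_bats"] = _group_richness(pres, ~bat)
            tbl["mammals_bats"] = _group_richness(pres, bat)
            tbl["mammals_small"] = _group_richness(pres, traits["is_small"].to_numpy())
            tbl["mammals_large"] = _group_richness(pres, traits["is_large"].to_numpy())
            tbl["mammals_common"] = _group_richness(pres, traits["is_common"].to_numpy())
        else:
            tbl["mammals_all"] = pres.sum(axis=0).astype(int)
    if bird_ranges is not None:
        bpres = presence_matrix(bird_ranges, grid)
        tbl["birds_all"] = bpres.sum(axis=0).astype(int)
        sizes = bpres.sum(axis=1)
        common = sizes >= np.median(sizes) if len(sizes) else np.zeros(0, bool)
        tbl["birds_common"] = _group_richness(bpres, common)

    if richness_direct is not None:
        for col in richness_direct.columns:
            if col != "cell_id":
                tbl[col] = richness_direct[col].to_numpy()

    if cell_fire_summary is not None:
        tbl = tbl.merge(cell_fire_summary, on="cell_id", how="left")
    logger.info(
        "cell table: %d cells, %d savanna, %d in analysis",
        n, int(tbl["is_savanna"].sum()), int(tbl["in_analysis"].sum()),
    )
    return tbl
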