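"""Grid geometry, date conventions and plain-text raster I/O.

The analysis grid is a regular lon/lat grid of quarter-degree-style cells
(default 0.5°), each subdivided into a square block of pixels (default
10 × 10, i.e. ~0.05° pixels, the scale of a MODIS burned-area pixel).
Cell ids are row-major from the north-west origin.

Dates are integer days since 2000-01-01 throughout; burn "year layers"
partition the record for storage only.

Rasters are stored as ESRI ASCII grids (text), one value per pixel,
row-major from the north-west corner, with nodata −1 for burn dates.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

EPOCH = datetime.date(2000, 1, 1)
NODATA = -1


def date_to_day(d: datetime.date) -> int:
    """Convert a calendar date to integer days since 2000-01-01."""
    return (d - EPOCH).days


def day_to_date(day: int) -> datetime.date:
    return EPOCH + datetime.timedelta(days=int(day))


def fifteenth_of_month(year: int, month: int) -> int:
    """Day index (since epoch) of the 15th of the given calendar month."""
    return date_to_day(datetime.date(year, month, 15))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Number of cells along latitude (rows, north to south) and
        longitude (columns, west to east).
    cell_size_deg : float
        Cell edge length in degrees.
    origin_lon, origin_lat : float
        North-west corner of the grid (lon of west edge, lat of north edge).
    pixels_per_cell : int
        Pixels along each cell edge; the pixel raster is
        (n_rows·pixels_per_cell) × (n_cols·pixels_per_cell).
    km_per_deg : float
        Planar scale used for all distance work (buffers, pixel areas);
        the synthetic landscape lives on this flat plane so no geodesy
        is required.
    """

    n_rows: int = 20
    n_cols: int = 20
    cell_size_deg: float = 0.5
    origin_lon: float = 20.0
    origin_lat: float = 0.0
    pixels_per_cell: int = 10
    km_per_deg: float = 111.0

    def __post_init__(self):
        if self.n_rows < 5 or self.n_cols < 5:
            raise ValueError(
                "grid must be at least 5x5 cells: the spatial model's "
                "adjacency structure needs interior neighbours"
            )

    # ---- derived geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_rows(self) -> int:
        return self.n_rows * self.pixels_per_cell

    @property
    def pixel_cols(self) -> int:
        return self.n_cols * self.pixels_per_cell

    @property
    def pixel_size_deg(self) -> float:
        return self.cell_size_deg / self.pixels_per_cell

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size_deg * self.km_per_deg) ** 2

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_deg * self.km_per_deg) ** 2

    # ---- indexing ---------------------------------------------------------
    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def cell_rowcol(self, cell_id: int) -> tuple[int, int]:
        return divmod(cell_id, self.n_cols)

    def cell_of_pixel(self, prow: int, pcol: int) -> int:
        return self.cell_id(prow // self.pixels_per_cell, pcol // self.pixels_per_cell)

    def pixel_center_lonlat(self, prow, pcol):
        """Lon/lat of pixel centers; accepts scalars or arrays."""
        lon = self.origin_lon + (np.asarray(pcol) + 0.5) * self.pixel_size_deg
        lat = self.origin_lat - (np.asarray(prow) + 0.5) * self.pixel_size_deg
        return lon, lat

    def lonlat_to_pixel(self, lon, lat):
        """Pixel (row, col) containing a lon/lat point (floor convention)."""
        pcol = np.floor((np.asarray(lon) - self.origin_lon) / self.pixel_size_deg).astype(int)
        prow = np.floor((self.origin_lat - np.asarray(lat)) / self.pixel_size_deg).astype(int)
        return prow, pcol

    def lonlat_to_cell(self, lon, lat):
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size_deg).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size_deg).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        cid = np.where(ok, row * self.n_cols + col, -1)
        return cid

    def cell_polygon(self, cell_id: int):
        """Cell footprint as a shapely box.

        Cells are half-open [west, east) × [south, north) so the grid
        tiles without double counting; the shapely polygon is closed but
        assignment ops always use the floor convention above.
        """
        row, col = self.cell_rowcol(cell_id)
        west = self.origin_lon + col * self.cell_size_deg
        north = self.origin_lat - row * self.cell_size_deg
        return box(west, north - self.cell_size_deg, west + self.cell_size_deg, north)

    def cell_centers(self):
        """(n_cells, 2) array of cell-center lon/lat, row-major."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size_deg
        lat = self.origin_lat - (rows + 0.5) * self.cell_size_deg
        return np.column_stack([lon, lat])

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size_deg": self.cell_size_deg,
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "pixels_per_cell": self.pixels_per_cell,
            "km_per_deg": self.km_per_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


# ---- ASCII raster I/O -----------------------------------------------------

def write_ascii_raster(path, array: np.ndarray, grid: GridSpec, nodata=NODATA) -> None:
    """Write a pixel raster as an ESRI ASCII grid (text).

    Row order is north to south, matching the array's row order.
    """
    arr = np.asarray(array)
    if arr.shape != (grid.pixel_rows, grid.pixel_cols):
        raise ValueError(f"array shape {arr.shape} does not match grid pixels")
    is_int = np.issubdtype(arr.dtype, np.integer)
    yll = grid.origin_lat - grid.n_rows * grid.cell_size_deg
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.pixel_cols}\n")
        fh.write(f"nrows {grid.pixel_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.pixel_size_deg!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if is_int else "%.10g"
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_raster(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    if float(header.get("nodata_value", NODATA)).is_integer() and np.allclose(
        arr, np.round(arr)
    ):
        arr = arr.astype(np.int64)
    arr = arr.reshape(int(header["nrows"]), int(header["ncols"]))
    return arr, header


def queen_adjacency(n_rows: int, n_cols: int, mask: np.ndarray | None = None):
    """Sparse symmetric queen (8-neighbour) adjacency over grid cells.

    Parameters
    ----------
    mask : bool array of shape (n_rows, n_cols), optional
        Only cells where mask is True are included; the returned matrix
        is indexed by position within the masked subset, and the second
        return value maps subset index -> full row-major cell id.
    """
    from scipy import sparse

    if mask is None:
        mask = np.ones((n_rows, n_cols), bool)
    idx = -np.ones((n_rows, n_cols), int)
    cells = np.argwhere(mask)
    idx[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
    rows, cols = [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r2 = cells[:, 0] + dr
            c2 = cells[:, 1] + dc
            ok = (r2 >= 0) & (r2 < n_rows) & (c2 >= 0) & (c2 < n_cols)
            ok[ok] &= mask[r2[ok], c2[ok]]
            rows.append(idx[cells[ok, 0], cells[ok, 1]])
            cols.append(idx[r2[ok], c2[ok]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(cells), len(cells))
    ).tocsr()
    A.data[:] = 1.0  # duplicates summed by coo -> reset
    full_ids = cells[:, 0] * n_cols + cells[:, 1]
    return A, full_ids
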