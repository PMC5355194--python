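"""Raster geometry shared by every stage of the pipeline.

All grids in the package live on a single cell-centered lon/lat lattice with
latitude decreasing row-wise (row 0 is the northernmost row).  A
:class:`GridSpec` carries the geometry; data are plain ``float64``/``bool``
numpy arrays of shape ``(nrows, ncols)`` with ``NaN`` marking undefined cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    nrows, ncols
        Grid shape.
    cellsize
        Cell edge length in degrees (square cells).
    lon0
        Longitude of the center of column 0.
    lat0
        Latitude of the center of row 0 (the northernmost row); latitude
        decreases with row index.
    """

    nrows: int
    ncols: int
    cellsize: float
    lon0: float
    lat0: float

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def size(self) -> int:
        return self.nrows * self.ncols

    def lons(self) -> np.ndarray:
        return self.lon0 + self.cellsize * np.arange(self.ncols)

    def lats(self) -> np.ndarray:
        return self.lat0 - self.cellsize * np.arange(self.nrows)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of shape ``(nrows, ncols)``."""
        lon, lat = np.meshgrid(self.lons(), self.lats())
        return lon, lat

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        col = int(np.clip(round((lon - self.lon0) / self.cellsize), 0, self.ncols - 1))
        row = int(np.clip(round((self.lat0 - lat) / self.cellsize), 0, self.nrows - 1))
        return row, col

    def coarsen(self, factor: int) -> "GridSpec":
        """Spec of the grid obtained by block-aggregating with ``factor``."""
        if factor < 1:
            raise ValueError("aggregation factor must be >= 1")
        nr = -(-self.nrows // factor)
        nc = -(-self.ncols // factor)
        half = (factor - 1) / 2.0
        return GridSpec(
            nrows=nr,
            ncols=nc,
            cellsize=self.cellsize * factor,
            lon0=self.lon0 + half * self.cellsize,
            lat0=self.lat0 - half * self.cellsize,
        )


@dataclass
class ElevationGrid:
    """Present-day elevation in meters; negative values are below present
    sea level (bathymetry), positive values are land."""

    spec: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError("elevation array shape does not match grid spec")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("elevation grid contains non-finite values")
        if not np.any(self.values < 0):
            raise ValueError("elevation grid has no sea cells (no values < 0)")

    @property
    def sea_mask(self) -> np.ndarray:
        """Cells below present sea level."""
        return self.values < 0


@dataclass
class ClimateGrid:
    """Sea surface temperature (deg C) on the same geometry as the
    elevation grid it is paired with.  NaN marks land cells."""

    spec: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError("climate array shape does not match grid spec")

    def value_at_sea(self, lon: float, lat: float) -> float:
        """SST at the sea cell nearest (lon, lat).

        If the nearest cell is land (NaN) the nearest defined cell is used.
        """
        row, col = self.spec.nearest_cell(lon, lat)
        v = self.values[row, col]
        if np.isfinite(v):
            return float(v)
        ok = np.isfinite(self.values)
        if not ok.any():
            raise ValueError("climate grid has no defined sea cells")
        rr, cc = np.nonzero(ok)
        d2 = (rr - row) ** 2 + (cc - col) ** 2
        i = int(np.argmin(d2))
        return float(self.values[rr[i], cc[i]])


def great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in kilometers."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def aggregate_to_analysis_grid(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a fine grid onto a coarser analysis grid.

    Each ``factor x factor`` block is reduced to the mean of its defined
    (non-NaN) cells; a block that is entirely undefined stays NaN.  Trailing
    partial blocks (when a dimension is not divisible by ``factor``) are
    averaged over the cells they do contain.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    fine = np.asarray(fine, dtype=float)
    if fine.ndim != 2:
        raise ValueError("expected a 2D grid")
    nr, nc = fine.shape
    nr_c = -(-nr // factor)
    nc_c = -(-nc // factor)
    out = np.full((nr_c, nc_c), np.nan)
    for i in range(nr_c):
        for j in range(nc_c):
            block = fine[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            if np.isfinite(block).any():
                out[i, j] = np.nanmean(block)
    return out


def aggregate_fraction(fine_bool: np.ndarray, factor: int) -> np.ndarray:
    """Fraction of True cells per aggregation block (land-fraction helper)."""
    return aggregate_to_analysis_grid(np.asarray(fine_bool, dtype=float), factor)
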