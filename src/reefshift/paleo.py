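"""Paleo-habitat reconstruction from sediment-core series and bathymetry.

The reconstruction turns a set of sediment-core time series (sea surface
temperature and sea level, on a 1,000-year age grid) plus a present-day
bathymetry and a pre-warming SST baseline into one boolean reef-suitability
grid per time slice.  A cell is suitable at time *t* when it is

1. immerged under the contemporaneous sea stand,
2. within the reef depth window below that sea stand (default 0-100 m), and
3. at or above a thermal threshold after applying the basin-mean SST anomaly
   of slice *t* to the baseline map.

Anomalies are applied as a single basin-wide additive shift: with few cores
available through the full Quaternary a spatially interpolated anomaly field
would be mostly extrapolation, so the cross-core mean is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import ClimateGrid, ElevationGrid, GridSpec

AGE_STEP_KA = 1.0  # core series live on a regular 1,000-yr age grid


@dataclass
class PaleoSeries:
    """One sediment-core record: SST (deg C) or sea level (m relative to
    present) against age in ka BP, on a strictly increasing age grid."""

    core_id: str
    lon: float
    lat: float
    kind: str  # "sst" | "sea_level"
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("sst", "sea_level"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.ages.ndim != 1 or self.ages.shape != self.values.shape:
            raise ValueError("ages and values must be 1D arrays of equal length")
        if self.ages.size >= 2 and not np.all(np.diff(self.ages) > 0):
            raise ValueError("ages must be strictly increasing")


@dataclass
class AnomalyTable:
    """Per-slice basin state: mean SST anomaly across cores and sea level."""

    ages: np.ndarray
    sst_anomaly: np.ndarray  # deg C, mean over cores
    sea_level: np.ndarray  # m relative to present

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.sst_anomaly = np.asarray(self.sst_anomaly, dtype=float)
        self.sea_level = np.asarray(self.sea_level, dtype=float)
        n = self.ages.size
        if self.sst_anomaly.size != n or self.sea_level.size != n:
            raise ValueError("anomaly table columns must share one age grid")

    def __len__(self) -> int:
        return self.ages.size

    def index_of(self, age_ka: float) -> int:
        i = np.flatnonzero(np.isclose(self.ages, age_ka))
        if i.size == 0:
            raise KeyError(f"age {age_ka} ka not in anomaly table")
        return int(i[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_ka": self.ages, "sst_anomaly_C": self.sst_anomaly, "sea_level_m": self.sea_level}
        )


@dataclass
class SuitabilityStack:
    """Time-ordered boolean reef-suitability grids.

    ``masks[t]`` is True where the cell is reef-suitable at slice ``t``;
    ``ages`` gives the slice ages in ka BP (same order as masks).
    """

    spec: GridSpec
    ages: np.ndarray
    masks: np.ndarray = field(repr=False)  # (T, nrows, ncols) bool
    threshold_C: float = np.nan
    depth_window: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.masks.ndim != 3 or self.masks.shape[0] != self.ages.size:
            raise ValueError("masks must be (T, nrows, ncols) matching ages")
        if self.masks.shape[1:] != self.spec.shape:
            raise ValueError("mask shape does not match grid spec")

    @property
    def n_timesteps(self) -> int:
        return self.masks.shape[0]

    def occupancy(self) -> np.ndarray:
        """Number of slices each cell was suitable (the K of the isolation
        statistic)."""
        return self.masks.sum(axis=0)


@dataclass
class ReconstructionConfig:
    """Options for the habitat reconstruction.

    thresholds : thermal thresholds (deg C) swept in sensitivity analysis;
        defaults to 23..28 by 1 deg C.
    depth_window : (min, max) water depth in m below the contemporaneous sea
        level within which reefs can grow; default (0, 100].
    aggregation_factor : fine-to-analysis cell ratio (block size).
    land_fraction_cutoff : analysis cells with at least this land fraction
        are dropped.
    """

    thresholds: tuple[float, ...] = (23.0, 24.0, 25.0, 26.0, 27.0, 28.0)
    depth_window: tuple[float, float] = (0.0, 100.0)
    aggregation_factor: int = 1
    land_fraction_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if len(self.thresholds) == 0:
            raise ValueError("at least one thermal threshold is required")
        if self.depth_window[0] < 0:
            raise ValueError("minimum reef depth must be >= 0")
        if self.depth_window[1] <= self.depth_window[0]:
            raise ValueError("depth window must have max > min")
        if self.aggregation_factor < 1:
            raise ValueError("aggregation factor must be >= 1")


# ---------------------------------------------------------------------------
# core QC and regridding


def regrid_and_qc(cores: Sequence[PaleoSeries]) -> tuple[list[PaleoSeries], pd.DataFrame]:
    """Interpolate all cores to the common 1,000-yr age grid and cross-check
    them with pairwise Pearson correlations.

    The common grid spans the union of the cores' age ranges; each series is
    linearly interpolated within its own span and left NaN outside it.
    Correlations use pairwise-complete slices; pairs with fewer than two
    overlapping slices are NaN.
    """
    cores = list(cores)
    if not cores:
        raise ValueError("empty core list")
    for c in cores:
        if c.ages.size < 2:
            raise ValueError(f"core {c.core_id!r} covers fewer than 2 timesteps")
    lo = min(c.ages.min() for c in cores)
    hi = max(c.ages.max() for c in cores)
    grid = np.arange(np.floor(lo), np.floor(hi) + AGE_STEP_KA / 2, AGE_STEP_KA)

    regridded: list[PaleoSeries] = []
    for c in cores:
        vals = np.interp(grid, c.ages, c.values, left=np.nan, right=np.nan)
        regridded.append(
            PaleoSeries(core_id=c.core_id, lon=c.lon, lat=c.lat, kind=c.kind, ages=grid.copy(), values=vals)
        )

    ids = [c.core_id for c in regridded]
    mat = np.column_stack([c.values for c in regridded])
    n = len(ids)
    corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            ok = np.isfinite(mat[:, i]) & np.isfinite(mat[:, j])
            if ok.sum() >= 2:
                xi, xj = mat[ok, i], mat[ok, j]
                if np.std(xi) > 0 and np.std(xj) > 0:
                    corr[i, j] = corr[j, i] = np.corrcoef(xi, xj)[0, 1]
                elif np.allclose(xi, xj):
                    # constant pair: correlation undefined, but identical
                    # records are trivially consistent
                    corr[i, j] = corr[j, i] = 1.0
    np.fill_diagonal(corr, 1.0)
    return regridded, pd.DataFrame(corr, index=ids, columns=ids)


def compute_anomalies(cores: Sequence[PaleoSeries], baseline: ClimateGrid) -> AnomalyTable:
    """Anchor each SST core to the baseline map and average the anomalies.

    Per core and slice, anomaly = core SST(t) - baseline SST at the core's
    (nearest sea) cell; the table stores the unweighted cross-core mean per
    slice, plus the sea level from the sea-level series (averaged if several).
    """
    sst = [c for c in cores if c.kind == "sst"]
    sl = [c for c in cores if c.kind == "sea_level"]
    if not sst:
        raise ValueError("no SST cores supplied")
    if not sl:
        raise ValueError("no sea-level series supplied")
    regridded, _ = regrid_and_qc(list(cores))
    by_id = {c.core_id: c for c in regridded}
    grid = regridded[0].ages

    anom = np.full((len(sst), grid.size), np.nan)
    for k, c in enumerate(sst):
        ref = baseline.value_at_sea(c.lon, c.lat)
        anom[k] = by_id[c.core_id].values - ref
    with np.errstate(invalid="ignore"):
        mean_anom = np.nanmean(anom, axis=0)

    sl_mat = np.vstack([by_id[c.core_id].values for c in sl])
    with np.errstate(invalid="ignore"):
        sea_level = np.nanmean(sl_mat, axis=0)

    ok = np.isfinite(mean_anom) & np.isfinite(sea_level)
    return AnomalyTable(ages=grid[ok], sst_anomaly=mean_anom[ok], sea_level=sea_level[ok])


# ---------------------------------------------------------------------------
# hindcasting and suitability


def hindcast_sst(baseline: ClimateGrid, anomalies: AnomalyTable, age_ka: float) -> ClimateGrid:
    """Baseline SST shifted by the basin-mean anomaly of slice ``age_ka``.

    The shift is uniform over all cells, so spatial SST ranking is preserved.
    """
    t = anomalies.index_of(age_ka)
    return ClimateGrid(spec=baseline.spec, values=baseline.values + anomalies.sst_anomaly[t])


def immersion_mask(elev: ElevationGrid, sea_level_m: float) -> np.ndarray:
    """Cells under water at a sea stand of ``sea_level_m`` (m rel. present).

    A cell is immerged iff its elevation h < s(t); contemporaneous water
    depth is d = s(t) - h.
    """
    return elev.values < sea_level_m


def contemporaneous_depth(elev: ElevationGrid, sea_level_m: float) -> np.ndarray:
    """Water depth (m) under a given sea stand; negative where exposed."""
    return sea_level_m - elev.values


def build_suitability_stack(
    elev: ElevationGrid,
    baseline: ClimateGrid,
    anomalies: AnomalyTable,
    config: ReconstructionConfig,
    threshold_C: float,
) -> SuitabilityStack:
    """Overlay thermal and depth envelopes into one mask per time slice.

    Suitable(t, cell) = immerged(t) AND depth_min < d(t) <= depth_max AND
    hindcast SST(t) >= threshold.  Cells with undefined baseline SST are
    never thermally suitable.
    """
    if not any(np.isclose(threshold_C, th) for th in config.thresholds):
        raise ValueError(f"threshold {threshold_C} not in config.thresholds")
    dmin, dmax = config.depth_window
    masks = np.zeros((len(anomalies), *elev.spec.shape), dtype=bool)
    for t in range(len(anomalies)):
        s_t = anomalies.sea_level[t]
        depth = contemporaneous_depth(elev, s_t)
        sst = baseline.values + anomalies.sst_anomaly[t]
        with np.errstate(invalid="ignore"):
            thermal = sst >= threshold_C
        masks[t] = (depth > dmin) & (depth <= dmax) & thermal & np.isfinite(sst)
    return SuitabilityStack(
        spec=elev.spec,
        ages=anomalies.ages.copy(),
        masks=masks,
        threshold_C=threshold_C,
        depth_window=config.depth_window,
    )


def traversability_masks(elev: ElevationGrid, anomalies: AnomalyTable) -> np.ndarray:
    """Per-slice sea masks under the contemporaneous sea stand.

    Dispersal cost paths may cross any immerged cell; land is a barrier.
    Low sea stands therefore both remove habitat and create barriers.
    """
    masks = np.zeros((len(anomalies), *elev.spec.shape), dtype=bool)
    for t in range(len(anomalies)):
        masks[t] = immersion_mask(elev, anomalies.sea_level[t])
    return masks


# ---------------------------------------------------------------------------
# CSV I/O


def cores_to_frame(cores: Iterable[PaleoSeries]) -> pd.DataFrame:
    rows = []
    for c in cores:
        for a, v in zip(c.ages, c.values):
            rows.append((c.core_id, c.lon, c.lat, c.kind, a, v))
    return pd.DataFrame(rows, columns=["core_id", "lon", "lat", "kind", "age_ka", "value"])


def cores_from_frame(df: pd.DataFrame) -> list[PaleoSeries]:
    out = []
    for cid, g in df.groupby("core_id", sort=False):
        g = g.sort_values("age_ka")
        out.append(
            PaleoSeries(
                core_id=str(cid),
                lon=float(g["lon"].iloc[0]),
                lat=float(g["lat"].iloc[0]),
                kind=str(g["kind"].iloc[0]),
                ages=g["age_ka"].to_numpy(),
                values=g["value"].to_numpy(),
            )
        )
    return out
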