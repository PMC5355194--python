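"""Time-integrated isolation from stable reef areas (the IREF statistic).

For each time slice the least-cost distance from every sea cell to the
nearest reef-suitable cell is computed on the 8-connected grid graph, with
step costs equal to the great-circle distance between cell centers and land
acting as a barrier.  Summing those distances over slices and dividing by
the number of slices the cell itself was suitable gives the isolation
statistic:

    IREF(cell) = C(cell) / K(cell),
    C = sum over slices of distance-to-nearest-suitable,
    K = number of slices the cell was suitable.

IREF is 0 for cells that stayed suitable through every slice (stable areas /
refugia) and grows with both the frequency and the remoteness of local
habitat collapse.  Cells never suitable (K = 0) are undefined.

Two policies keep the statistic finite for analyzable cells:

* slices with no suitable cell anywhere ("global collapse") are skipped and
  counted, rather than contributing unbounded distances;
* sea cells disconnected from all suitable habitat at a slice (isolated
  seas) contribute the grid-diagonal great-circle length as a capped
  penalty instead of infinity, so downstream regressions see finite
  predictors.  The cap is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import GridSpec, great_circle_km
from .paleo import SuitabilityStack

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class IsolationMap:
    """Per-cell isolation statistic and its ingredients.

    cumulative_km : C, summed least-cost distance over non-collapsed slices.
    occupancy : K, number of slices the cell was suitable.
    iref : C / K where K > 0, NaN otherwise.
    """

    spec: GridSpec
    cumulative_km: np.ndarray = field(repr=False)
    occupancy: np.ndarray = field(repr=False)
    iref: np.ndarray = field(repr=False)
    n_timesteps: int = 0
    n_collapsed: int = 0
    unreachable_cap_km: float = np.nan


def grid_graph(traversable: np.ndarray, spec: GridSpec, cost_scale: float = 1.0) -> csr_matrix:
    """Sparse 8-connected graph over the traversable cells of a grid.

    Edge weights are great-circle distances (km) between cell centers;
    diagonal steps cost their true geodesic length.  Non-traversable cells
    keep their node index but have no incident edges.
    """
    traversable = np.asarray(traversable, dtype=bool)
    if traversable.shape != spec.shape:
        raise ValueError("traversability mask shape does not match grid spec")
    nr, nc = spec.shape
    lon, lat = spec.cell_centers()
    idx = np.arange(nr * nc).reshape(nr, nc)

    rows, cols, weights = [], [], []
    for dr, dc in _NEIGHBOR_OFFSETS:
        if dr < 0 or (dr == 0 and dc < 0):
            continue  # each undirected edge once; symmetrized below
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = traversable[r0:r1, c0:c1] & traversable[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not ok.any():
            continue
        a, b = a[ok], b[ok]
        w = great_circle_km(lon.ravel()[a], lat.ravel()[a], lon.ravel()[b], lat.ravel()[b])
        rows.append(a)
        cols.append(b)
        weights.append(w * cost_scale)
    if not rows:
        n = nr * nc
        return csr_matrix((n, n))
    r = np.concatenate(rows + cols)
    c = np.concatenate(cols + rows)
    w = np.concatenate(weights + weights)
    n = nr * nc
    return csr_matrix((w, (r, c)), shape=(n, n))


def distance_to_suitable(
    graph: csr_matrix, suitable: np.ndarray, traversable: np.ndarray
) -> np.ndarray:
    """Least-cost distance (km) from every traversable cell to the nearest
    suitable cell.

    Multi-source Dijkstra over the barrier-aware grid graph: suitable cells
    get 0, unreachable traversable cells get +inf, non-traversable cells NaN.
    """
    suitable = np.asarray(suitable, dtype=bool)
    traversable = np.asarray(traversable, dtype=bool)
    if not suitable.any():
        raise ValueError("no suitable cells at this timestep (global collapse)")
    if np.any(suitable & ~traversable):
        raise ValueError("suitable cells must be traversable")
    sources = np.flatnonzero(suitable.ravel())
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    out = dist.reshape(suitable.shape).astype(float)
    out[~traversable] = np.nan
    return out


def compute_isolation(
    stack: SuitabilityStack,
    traversable: np.ndarray,
    cost_scale: float = 1.0,
    unreachable_cap_km: float | None = None,
) -> IsolationMap:
    """Integrate per-slice least-cost distances into the isolation map.

    Parameters
    ----------
    stack
        Per-slice suitability masks.
    traversable
        Per-slice sea masks, shape (T, nrows, ncols); must contain the
        suitable set at every slice.
    cost_scale
        Multiplier on all step costs (useful for unit tests in cell units).
    unreachable_cap_km
        Penalty distance for traversable-but-disconnected cells; defaults to
        the great-circle length of the grid diagonal (times cost_scale).
    """
    if stack.n_timesteps < 1:
        raise ValueError("need at least one timestep")
    traversable = np.asarray(traversable, dtype=bool)
    if traversable.shape != stack.masks.shape:
        raise ValueError("traversability stack shape must match suitability stack")
    if np.any(stack.masks & ~traversable):
        raise ValueError("suitable cells must be traversable at every slice")

    spec = stack.spec
    if unreachable_cap_km is None:
        lon, lat = spec.cell_centers()
        unreachable_cap_km = float(
            great_circle_km(lon[0, 0], lat[0, 0], lon[-1, -1], lat[-1, -1]) * cost_scale
        )

    cumulative = np.zeros(spec.shape)
    ever_sea = traversable.any(axis=0)
    n_collapsed = 0
    graph_cache: dict[bytes, csr_matrix] = {}
    for t in range(stack.n_timesteps):
        suit_t = stack.masks[t]
        trav_t = traversable[t]
        if not suit_t.any():
            n_collapsed += 1
            continue
        key = np.packbits(trav_t).tobytes()
        graph = graph_cache.get(key)
        if graph is None:
            graph = grid_graph(trav_t, spec, cost_scale=cost_scale)
            graph_cache[key] = graph
        dist = distance_to_suitable(graph, suit_t, trav_t)
        dist = np.where(np.isinf(dist), unreachable_cap_km, dist)
        # exposed cells accrue no distance this slice: they are land, not
        # habitat waiting to be reached
        cumulative += np.where(trav_t, np.nan_to_num(dist, nan=0.0), 0.0)

    if n_collapsed == stack.n_timesteps:
        raise ValueError("all timesteps collapsed: no suitable habitat anywhere in the window")

    occupancy = stack.occupancy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        iref = np.where(occupancy > 0, cumulative / occupancy, np.nan)
    cumulative = np.where(ever_sea, cumulative, np.nan)
    return IsolationMap(
        spec=spec,
        cumulative_km=cumulative,
        occupancy=stack.occupancy(),
        iref=iref,
        n_timesteps=stack.n_timesteps,
        n_collapsed=n_collapsed,
        unreachable_cap_km=unreachable_cap_km,
    )
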