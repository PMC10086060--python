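"""Brownian bridge movement model (BBMM) and stopover delineation.

The BBMM treats the path between successive GPS fixes as a conditioned
Brownian motion: at fractional time ``a`` along a bridge of duration
``T``, the animal's position is bivariate normal around the
time-interpolated endpoints with variance

    s2(a) = T * a * (1 - a) * sigma2_m + (1 - a)^2 * err^2 + a^2 * err^2,

where ``sigma2_m`` is the Brownian motion variance (m^2 per minute — the
convention of the field's BBMM software; the variance gate threshold is
in these units) and ``err`` the GPS location error.  ``sigma2_m`` is
estimated by maximising the leave-one-out likelihood of each interior fix
under the bridge joining its neighbours.  The utilization distribution
(UD) is the time-weighted average of bridge occupancy densities on a
150-m grid; high-use stopovers are the connected components of the 10%
highest-density isopleth occupied for at least 3 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .tracks import Track, UDGrid, _accumulate_gaussian, _make_grid, isopleth

__all__ = [
    "BBMMResult",
    "StopoverSet",
    "estimate_motion_variance",
    "bbmm_ud",
    "stopover_days",
    "stopover_geojson",
    "variance_gate",
]

MOTION_VARIANCE_GATE = 8000.0  # m^2/min; larger values flag unreliable UDs
MAX_LAG_HOURS = 8.0  # no bridges across longer fix gaps
LOCATION_ERROR_M = 20.0


@dataclass
class BBMMResult:
    motion_variance: float  # m^2/min
    ud: UDGrid
    at_bound: bool = False

    @property
    def cell_m(self) -> float:
        return self.ud.cell_m


@dataclass
class StopoverSet:
    """High-use stopovers of one migration."""

    stopovers: pd.DataFrame  # stopover_id, n_cells, n_fixes, days, x, y
    total_days: float
    labels: np.ndarray | None = None  # component id per UD grid cell (0 = none)


def _loo_terms(track: Track, max_lag_hours: float):
    """Per-interior-fix quantities for the leave-one-out likelihood."""
    t_min = track.t * 1440.0  # minutes
    xy = track.xy
    T = t_min[2:] - t_min[:-2]
    ok = T <= 2.0 * max_lag_hours * 60.0
    a = (t_min[1:-1] - t_min[:-2]) / T
    mu = (1.0 - a)[:, None] * xy[:-2] + a[:, None] * xy[2:]
    d2 = ((xy[1:-1] - mu) ** 2).sum(axis=1)
    return T[ok], a[ok], d2[ok]


def estimate_motion_variance(
    track: Track,
    location_error: float = LOCATION_ERROR_M,
    max_lag_hours: float = MAX_LAG_HOURS,
    bounds: tuple[float, float] = (1e-4, 1e6),
) -> tuple[float, bool]:
    """Maximum leave-one-out-likelihood Brownian motion variance (m^2/min).

    Each interior fix is scored as bivariate normal around the linear
    interpolation of its neighbours; a 1-D bounded search maximises the
    summed log-likelihood.  Returns ``(sigma2_m, at_bound)``; the flag
    marks an optimiser pinned at a search bound (e.g. a noiseless
    constant-velocity track, whose interior fixes are interpolated
    exactly).
    """
    if len(track) < 3:
        raise ValueError("need at least 3 fixes to estimate motion variance")
    T, a, d2 = _loo_terms(track, max_lag_hours)
    if T.size == 0:
        raise ValueError("no fix triplet within the maximum bridging lag")
    err2 = location_error**2

    def nll(sigma2: float) -> float:
        v = T * a * (1.0 - a) * sigma2 + ((1.0 - a) ** 2 + a**2) * err2
        return float(np.sum(np.log(v) + d2 / (2.0 * v)))

    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    sigma2 = float(res.x)
    span = bounds[1] - bounds[0]
    at_bound = sigma2 - bounds[0] < 1e-2 * span * 1e-4 or bounds[1] - sigma2 < 1e-3 * span
    return sigma2, at_bound


def bbmm_ud(
    track: Track,
    sigma2_m: float,
    cell_m: float = 150.0,
    location_error: float = LOCATION_ERROR_M,
    max_lag_hours: float = MAX_LAG_HOURS,
    grid: UDGrid | None = None,
    step_minutes: float = 15.0,
) -> BBMMResult:
    """Discretise the Brownian-bridge UD of a cleaned track on a grid.

    Each bridge's occupancy integral is evaluated at regular time steps;
    every integration point deposits its exact cell-integrated Gaussian
    mass (CDF differences, so kernels narrower than a cell do not alias).
    Bridges across gaps longer than ``max_lag_hours`` are excluded.  The
    UD is normalised to sum 1.
    """
    if sigma2_m <= 0:
        raise ValueError("motion variance must be positive")
    t_min = track.t * 1440.0
    xy = track.xy
    if grid is None:
        max_T = min(np.diff(t_min).max(), max_lag_hours * 60.0)
        sd_max = np.sqrt(0.25 * max_T * sigma2_m + location_error**2)
        grid = _make_grid(xy, cell_m, buffer_m=5.0 * sd_max + cell_m)
    else:
        if (
            xy[:, 0].min() < grid.x_edges[0]
            or xy[:, 0].max() > grid.x_edges[-1]
            or xy[:, 1].min() < grid.y_edges[0]
            or xy[:, 1].max() > grid.y_edges[-1]
        ):
            raise ValueError("grid does not cover the track extent")
        grid = UDGrid(grid.x_edges, grid.y_edges, np.zeros_like(grid.p))
    err2 = location_error**2
    total_w = 0.0
    for i in range(len(xy) - 1):
        T = t_min[i + 1] - t_min[i]
        if T <= 0 or T > max_lag_hours * 60.0:
            continue
        k = max(int(np.ceil(T / step_minutes)), 3)
        alphas = (np.arange(k) + 0.5) / k
        w = T / k
        for a in alphas:
            mx, my = (1.0 - a) * xy[i] + a * xy[i + 1]
            s2 = T * a * (1.0 - a) * sigma2_m + ((1.0 - a) ** 2 + a**2) * err2
            _accumulate_gaussian(grid, mx, my, np.sqrt(s2), w)
            total_w += w
    if total_w == 0:
        raise ValueError("no bridge within the maximum time lag")
    tot = grid.p.sum()
    if tot <= 0:
        raise ValueError("grid does not cover the track")
    grid.p /= tot
    return BBMMResult(motion_variance=float(sigma2_m), ud=grid)


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def stopover_days(
    track: Track,
    bbmm: BBMMResult,
    mass: float = 0.10,
    min_days: float = 3.0,
) -> StopoverSet:
    """Delineate high-use stopovers and count residence days.

    The ``mass`` (10%) highest-density isopleth of the UD is split into
    8-connected components; each component's residence time is its fix
    count divided by the fix rate (days = n_fixes * fix_interval / 24).
    Components below ``min_days`` are dropped.  An empty set is a valid
    outcome: some migrants never linger 3 days anywhere.
    """
    mask = isopleth(bbmm.ud, mass)
    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONN)
    iy, ix = bbmm.ud.cell_of(track.df["x"].to_numpy(), track.df["y"].to_numpy())
    fix_labels = labels[iy, ix]
    rows = []
    kept = 0
    keep_labels = np.zeros_like(labels)
    for comp in range(1, n_comp + 1):
        n_fix = int((fix_labels == comp).sum())
        days = n_fix * track.fix_interval / 24.0
        if days < min_days:
            continue
        kept += 1
        keep_labels[labels == comp] = kept
        cells = labels == comp
        cy, cx = np.nonzero(cells)
        rows.append(
            dict(
                stopover_id=kept,
                n_cells=int(cells.sum()),
                n_fixes=n_fix,
                days=days,
                x=float(bbmm.ud.x_centers[cx].mean()),
                y=float(bbmm.ud.y_centers[cy].mean()),
            )
        )
    df = pd.DataFrame(
        rows, columns=["stopover_id", "n_cells", "n_fixes", "days", "x", "y"]
    )
    return StopoverSet(
        stopovers=df, total_days=float(df["days"].sum()), labels=keep_labels
    )


def stopover_geojson(stops: StopoverSet, ud: UDGrid) -> dict:
    """Stopover polygons as a GeoJSON FeatureCollection.

    Each stopover's grid cells are dissolved into one (multi)polygon in the
    projected coordinate system; ``days`` and ``n_fixes`` ride along as
    feature properties.
    """
    from shapely import box, unary_union
    from shapely.geometry import mapping

    if stops.labels is None:
        raise ValueError("stopover set carries no grid labels")
    features = []
    for _, row in stops.stopovers.iterrows():
        iy, ix = np.nonzero(stops.labels == row["stopover_id"])
        cells = [
            box(ud.x_edges[j], ud.y_edges[i], ud.x_edges[j + 1], ud.y_edges[i + 1])
            for i, j in zip(iy, ix)
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(unary_union(cells)),
                "properties": {
                    "stopover_id": int(row["stopover_id"]),
                    "days": float(row["days"]),
                    "n_fixes": int(row["n_fixes"]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def variance_gate(
    motion_variance: float, threshold: float = MOTION_VARIANCE_GATE
) -> bool:
    """True when the animal-year's UD is usable (variance not above gate)."""
    return motion_variance <= threshold
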