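"""Per-pixel green-up phenology: double-logistic NDVI curves and the
Instantaneous Rate of Green-up (IRG).

The model for a scaled NDVI annual time series is the difference of two
logistic ramps,

    NDVI(t) = 1/(1 + exp((xmidS - t)/scalS)) - 1/(1 + exp((xmidA - t)/scalA)),

with ``t`` continuous day-of-year, a spring inflection ``xmidS`` (scale
``scalS``, days) and an autumn inflection ``xmidA`` (scale ``scalA``).
IRG is the derivative of the *spring* component only; its maximum,
``1/(4 scalS)``, falls exactly on ``xmidS``, which therefore is the date
of peak green-up for the pixel.  The foraging penalty of being mismatched
with that peak is scored as the mean loss in IRG over the two weeks
bracketing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import least_squares

__all__ = [
    "PhenoCurve",
    "PhenoRaster",
    "DoubleLogisticModel",
    "PhenologyError",
    "scale_ndvi",
    "fit_double_logistic",
    "irg",
    "peak_irg_date",
    "loss_in_irg",
    "fit_pixels",
]


class PhenologyError(ValueError):
    """Series cannot be scaled or fitted (constant, senescent-only, divergent)."""


@dataclass(frozen=True)
class PhenoCurve:
    """Fitted double-logistic green-up parameters for one pixel."""

    xmidS: float
    scalS: float
    xmidA: float
    scalA: float
    fit_rss: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.scalS > 0 and self.scalA > 0):
            raise ValueError("logistic scales must be positive")
        if not self.xmidS < self.xmidA:
            raise ValueError("spring inflection must precede autumn inflection")

    def ndvi(self, t):
        """Scaled NDVI at day-of-year ``t``."""
        t = np.asarray(t, dtype=float)
        spring = 1.0 / (1.0 + np.exp((self.xmidS - t) / self.scalS))
        autumn = 1.0 / (1.0 + np.exp((self.xmidA - t) / self.scalA))
        return spring - autumn

    def irg(self, t):
        return irg(self, t)

    @property
    def peak_date(self) -> float:
        return self.xmidS


def scale_ndvi(days, values, winsorize: bool = True, limits=(2.0, 98.0)):
    """Affinely rescale an NDVI series to [0, 1].

    ``winsorize`` clips to the given percentiles first, absorbing snow/cloud
    spikes; with it off the map is exact min->0, max->1.  A constant series
    has no green-up signal and raises :class:`PhenologyError`.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape:
        raise ValueError("days and values must have equal length")
    if winsorize:
        lo, hi = np.percentile(values, limits)
        values = np.clip(values, lo, hi)
    vmin, vmax = values.min(), values.max()
    if vmax - vmin <= 0:
        raise PhenologyError("constant series cannot be scaled")
    return (values - vmin) / (vmax - vmin)


def _dl_model(params, t):
    xmidS, scalS, xmidA, scalA = params
    return 1.0 / (1.0 + np.exp((xmidS - t) / scalS)) - 1.0 / (
        1.0 + np.exp((xmidA - t) / scalA)
    )


class DoubleLogisticModel:
    """Nonlinear least-squares fit of the double-logistic curve to one
    scaled NDVI series.

    Multi-start initialisation: the spring inflection starts at the day of
    the largest positive first difference, the autumn inflection at the most
    negative one, and the spring scale is tried on a coarse grid because the
    double logistic has local optima.  ``fit`` returns the
    :class:`PhenoCurve` with the smallest residual sum of squares among
    converged starts; if none converges (or the series never greens up) a
    :class:`PhenologyError` is raised and raster-level code flags the pixel
    missing.
    """

    SCALS_STARTS = (3.0, 8.0, 15.0)
    SCALA_STARTS = (8.0, 15.0)

    def __init__(self, days, scaled):
        self.days = np.asarray(days, dtype=float)
        self.scaled = np.asarray(scaled, dtype=float)
        if self.days.size < 8:
            raise PhenologyError("need at least 8 observations spanning spring")

    def fit(self) -> PhenoCurve:
        t, y = self.days, self.scaled
        dy = np.diff(y)
        if np.all(dy <= 0):
            raise PhenologyError("monotone non-increasing series: no spring green-up")
        mid = 0.5 * (t[:-1] + t[1:])
        xmidS0 = mid[int(np.argmax(dy))]
        xmidA0 = mid[int(np.argmin(dy))]
        if xmidA0 <= xmidS0:  # senescence not sampled; place it past the data
            xmidA0 = t[-1] + 30.0
        lo = [t[0] - 60.0, 0.5, t[0] - 60.0, 0.5]
        hi = [t[-1] + 60.0, 90.0, t[-1] + 120.0, 90.0]

        best = None
        for s0 in self.SCALS_STARTS:
            for a0 in self.SCALA_STARTS:
                x0 = np.clip([xmidS0, s0, xmidA0, a0], lo, hi)
                try:
                    sol = least_squares(
                        lambda p: _dl_model(p, t) - y, x0, bounds=(lo, hi)
                    )
                except Exception:  # singular jacobian etc.
                    continue
                if not sol.success:
                    continue
                rss = float(2.0 * sol.cost)
                if best is None or rss < best[0]:
                    best = (rss, sol.x)
        if best is None:
            raise PhenologyError("no start converged")
        rss, (xs, ss, xa, sa) = best
        if not xs < xa:
            raise PhenologyError("fitted spring inflection after autumn inflection")
        return PhenoCurve(float(xs), float(ss), float(xa), float(sa), fit_rss=rss)


def fit_double_logistic(days, scaled) -> PhenoCurve:
    """Functional wrapper around :class:`DoubleLogisticModel`."""
    return DoubleLogisticModel(days, scaled).fit()


def irg(curve: PhenoCurve, t):
    """Instantaneous Rate of Green-up: d/dt of the spring logistic, per day.

    IRG(t) = exp((xmidS-t)/scalS) / (scalS * (1 + exp((xmidS-t)/scalS))^2);
    non-negative, symmetric about ``xmidS`` and maximal there at 1/(4 scalS).
    """
    t = np.asarray(t, dtype=float)
    e = np.exp((curve.xmidS - t) / curve.scalS)
    out = e / (curve.scalS * (1.0 + e) ** 2)
    return float(out) if out.ndim == 0 else out


def peak_irg_date(curve: PhenoCurve) -> float:
    """Date of peak IRG — analytically the spring inflection ``xmidS``."""
    return curve.xmidS


def loss_in_irg(curve: PhenoCurve) -> float:
    """Foraging penalty (percent): mean drop in IRG over offsets of 1..7
    days either side of the peak, relative to IRG at the peak.

    Approaches 0 for slow green-up (large ``scalS``) and grows as green-up
    becomes more rapid and fleeting, which is what makes mismatch costly
    near the distal (montane) end of a migration corridor.
    """
    offsets = np.concatenate([np.arange(-7, 0), np.arange(1, 8)])
    peak = irg(curve, curve.xmidS)
    vals = irg(curve, curve.xmidS + offsets)
    return float(np.mean(peak - vals) / peak * 100.0)


# ---------------------------------------------------------------------------
# Gridded phenology


@dataclass
class PhenoRaster:
    """Gridded per-cell double-logistic parameters over a migration corridor.

    The corridor runs along +x from its (southern) origin; coordinates are
    projected meters, ``cell_km`` the square cell edge.  ``peak_date`` is
    xmidS per cell; cells that failed to fit carry NaN and are flagged by
    ``missing``.
    """

    x_km: np.ndarray  # cell-centre distance along corridor, km, shape (nx,)
    y_km: np.ndarray  # cell-centre cross-corridor offset, km, shape (ny,)
    cell_km: float
    xmidS: np.ndarray  # (ny, nx)
    scalS: np.ndarray
    xmidA: np.ndarray
    scalA: np.ndarray
    missing: np.ndarray = field(default=None)  # bool (ny, nx)

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = ~np.isfinite(self.xmidS)

    @property
    def peak_date(self) -> np.ndarray:
        return self.xmidS

    @property
    def corridor_length_km(self) -> float:
        return float(self.x_km[-1] + self.cell_km / 2.0)

    def cell_index(self, x_m, y_m):
        """Grid indices (iy, ix) of projected-meter positions; -1 outside."""
        x_m = np.asarray(x_m, dtype=float)
        y_m = np.asarray(y_m, dtype=float)
        ix = np.floor(x_m / (self.cell_km * 1000.0)).astype(int)
        iy = np.floor(
            (y_m / 1000.0 - (self.y_km[0] - self.cell_km / 2.0)) / self.cell_km
        ).astype(int)
        bad = (ix < 0) | (ix >= self.x_km.size) | (iy < 0) | (iy >= self.y_km.size)
        ix = np.where(bad, -1, ix)
        iy = np.where(bad, -1, iy)
        return iy, ix

    def peak_at(self, x_m, y_m):
        """Per-position date of peak IRG; NaN outside the grid or at
        missing cells."""
        iy, ix = self.cell_index(x_m, y_m)
        out = np.where((ix >= 0) & (iy >= 0), self.xmidS[iy, ix], np.nan)
        return float(out) if out.ndim == 0 else out

    def curve_at(self, iy: int, ix: int) -> PhenoCurve:
        if self.missing[iy, ix]:
            raise PhenologyError(f"cell ({iy}, {ix}) flagged missing")
        return PhenoCurve(
            float(self.xmidS[iy, ix]),
            float(self.scalS[iy, ix]),
            float(self.xmidA[iy, ix]),
            float(self.scalA[iy, ix]),
        )

    def irg_grid(self, t: float) -> np.ndarray:
        """IRG of every cell at day ``t`` (NaN where missing)."""
        e = np.exp((self.xmidS - t) / self.scalS)
        return e / (self.scalS * (1.0 + e) ** 2)

    def loss_grid(self) -> np.ndarray:
        """Per-cell loss-in-IRG percent (vectorised ``loss_in_irg``)."""
        offsets = np.concatenate([np.arange(-7, 0), np.arange(1, 8)])
        e = np.exp(-offsets[:, None, None] / self.scalS[None, :, :])
        vals = e / (self.scalS[None, :, :] * (1.0 + e) ** 2)
        peak = 1.0 / (4.0 * self.scalS)
        return np.mean(peak[None] - vals, axis=0) / peak * 100.0

    # -- serialisation ------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {"y_km": self.y_km, "x_km": self.x_km}
        return xr.Dataset(
            {
                "xmidS": (("y_km", "x_km"), self.xmidS),
                "scalS": (("y_km", "x_km"), self.scalS),
                "xmidA": (("y_km", "x_km"), self.xmidA),
                "scalA": (("y_km", "x_km"), self.scalA),
                "peak_date": (("y_km", "x_km"), self.xmidS),
            },
            coords=coords,
            attrs={"cell_km": self.cell_km},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "PhenoRaster":
        ds = xr.open_dataset(path, engine="scipy")
        return cls(
            x_km=ds["x_km"].values,
            y_km=ds["y_km"].values,
            cell_km=float(ds.attrs["cell_km"]),
            xmidS=ds["xmidS"].values,
            scalS=ds["scalS"].values,
            xmidA=ds["xmidA"].values,
            scalA=ds["scalA"].values,
        )


def fit_pixels(df: pd.DataFrame, winsorize: bool = True) -> pd.DataFrame:
    """Fit every pixel of a long-format NDVI table.

    ``df`` columns: ``pixel_id``, ``day``, ``ndvi``.  Returns one row per
    pixel with the fitted parameters; pixels that cannot be scaled or fitted
    are kept with NaN parameters and ``missing=True``.
    """
    rows = []
    for pid, grp in df.groupby("pixel_id", sort=True):
        grp = grp.sort_values("day")
        try:
            scaled = scale_ndvi(grp["day"], grp["ndvi"], winsorize=winsorize)
            curve = fit_double_logistic(grp["day"].to_numpy(), scaled)
            rows.append(
                dict(
                    pixel_id=pid,
                    xmidS=curve.xmidS,
                    scalS=curve.scalS,
                    xmidA=curve.xmidA,
                    scalA=curve.scalA,
                    fit_rss=curve.fit_rss,
                    missing=False,
                )
            )
        except PhenologyError as err:
            warnings.warn(f"pixel {pid} flagged missing: {err}")
            rows.append(
                dict(
                    pixel_id=pid,
                    xmidS=np.nan,
                    scalS=np.nan,
                    xmidA=np.nan,
                    scalA=np.nan,
                    fit_rss=np.nan,
                    missing=True,
                )
            )
    return pd.DataFrame(rows)
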