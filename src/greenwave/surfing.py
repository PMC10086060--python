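"""Green-wave surfing metrics.

Days-From-Peak (DFP) is the signed difference, in days, between the date
an animal occupies a location and that location's date of peak IRG.  The
sign convention is fixed repo-wide: DFP > 0 means *behind* the wave
(after local peak), DFP < 0 ahead of it; a perfect surfer scores 0.  The
same convention applies to start/end range mismatches (migration date
minus mean range peak date).

Per-fix DFP is averaged per day and per kilometre of corridor before any
population statistic, so animals with denser fix schedules do not weigh
more (pseudoreplication control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenology import PhenoRaster
from .tracks import MigrationWindow, SeasonalRange, Track

__all__ = [
    "SurfProfile",
    "WaveProfile",
    "days_from_peak",
    "aggregate_dfp",
    "range_mismatch",
    "wave_propagation",
    "weekly_wave_profile",
    "penalty_profile",
]


@dataclass
class SurfProfile:
    """Per-(day, km) mean DFP along one migration."""

    animal_year: str
    records: pd.DataFrame  # columns: day, km_bin, mean_dfp, n_fixes
    mean_dfp: float
    dfp_start: float = float("nan")
    dfp_end: float = float("nan")


@dataclass
class WaveProfile:
    """Per-km mean peak date and its signed propagation segments."""

    profile: pd.DataFrame  # columns: km_bin, mean_peak_date, direction
    segments: pd.DataFrame  # km_lo, km_hi, direction, slope, p_value, n_bins


def days_from_peak(track: Track, raster: PhenoRaster):
    """Per-fix DFP against the local cell's peak-IRG date.

    Returns ``(records, n_dropped)``; fixes in missing or off-raster cells
    are dropped and counted.  ``km`` is the fix's along-corridor distance
    (projection onto the corridor axis, not path length).
    """
    t = track.t
    x = track.df["x"].to_numpy()
    y = track.df["y"].to_numpy()
    peak = raster.peak_at(x, y)
    ok = np.isfinite(peak)
    rec = pd.DataFrame(
        {
            "t": t[ok],
            "x": x[ok],
            "y": y[ok],
            "km": x[ok] / 1000.0,
            "dfp": t[ok] - peak[ok],
        }
    )
    return rec, int((~ok).sum())


def aggregate_dfp(
    records: pd.DataFrame,
    animal_year: str = "",
    window: MigrationWindow | None = None,
) -> SurfProfile:
    """Collapse per-fix DFP to one mean per (day, 1-km bin).

    ``mean_dfp`` is the mean of the bin means; restricting to a migration
    window drops fixes outside [start, end].
    """
    if len(records) == 0:
        raise ValueError("no DFP records to aggregate")
    rec = records
    if window is not None and not window.resident:
        m = (rec["t"] >= window.start_date) & (rec["t"] <= window.end_date)
        rec = rec[m]
        if len(rec) == 0:
            raise ValueError("no DFP records inside the migration window")
    day = np.floor(rec["t"].to_numpy()).astype(int)
    km_bin = np.floor(rec["km"].to_numpy()).astype(int)
    g = (
        pd.DataFrame({"day": day, "km_bin": km_bin, "dfp": rec["dfp"].to_numpy()})
        .groupby(["day", "km_bin"], as_index=False)
        .agg(mean_dfp=("dfp", "mean"), n_fixes=("dfp", "size"))
    )
    return SurfProfile(
        animal_year=animal_year,
        records=g,
        mean_dfp=float(g["mean_dfp"].mean()),
    )


def range_mismatch(window: MigrationWindow, srange: SeasonalRange) -> float:
    """Signed start or end mismatch, days.

    Winter range: start date of spring migration minus the range's mean
    peak-IRG date (negative = departed ahead of the wave).  Summer range:
    the same with the end date.
    """
    if window.resident:
        raise ValueError("resident animal-year has no migration mismatch")
    if not np.isfinite(srange.mean_peak_date):
        raise ValueError("seasonal range has no mean peak date (no raster overlap)")
    date = window.start_date if srange.season == "winter" else window.end_date
    return float(date - srange.mean_peak_date)


def wave_propagation(
    raster: PhenoRaster,
    max_km: float = 240.0,
    smooth_km: int = 9,
    min_segment_km: int = 5,
) -> WaveProfile:
    """Characterise how the green wave propagates along the corridor.

    Mean peak date per 1-km bin (all corridor cells within ``max_km`` of
    the origin); direction of its rate of change — the sign of the finite
    difference of a ``smooth_km``-bin moving average, with runs shorter
    than ``min_segment_km`` merged into their longer neighbour so pixel
    noise cannot shatter the corridor into sub-scale segments; and one OLS
    regression of mean peak date on distance per same-direction segment
    (segments under 3 bins carry no regression).  A negative-direction
    segment is a wave propagating backwards toward the winter range.
    """
    km_bin = np.floor(np.repeat(raster.x_km[None, :], raster.y_km.size, axis=0))
    peaks = raster.peak_date
    ok = np.isfinite(peaks) & (km_bin <= max_km)
    df = (
        pd.DataFrame({"km_bin": km_bin[ok].astype(int), "peak": peaks[ok]})
        .groupby("km_bin", as_index=False)
        .agg(mean_peak_date=("peak", "mean"))
        .sort_values("km_bin", ignore_index=True)
    )
    sm = (
        df["mean_peak_date"]
        .rolling(smooth_km, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    diff = np.diff(sm)
    positive = np.r_[diff, diff[-1]] >= 0

    # runs of equal direction, then absorb sub-scale runs into neighbours
    runs: list[list] = []  # [length, positive?]
    for flag in positive:
        if runs and runs[-1][1] == flag:
            runs[-1][0] += 1
        else:
            runs.append([1, bool(flag)])
    while len(runs) > 1:
        lengths = [r[0] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_segment_km:
            break
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(runs)]
        j = max(neighbours, key=lambda k: runs[k][0])
        runs[i][1] = runs[j][1]  # adopt the dominant neighbour's direction
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][1] == r[1]:
                merged[-1][0] += r[0]
            else:
                merged.append(r)
        runs = merged
    direction = np.concatenate(
        [np.repeat("positive" if f else "negative", n) for n, f in runs]
    )
    df["direction"] = direction

    seg_rows = []
    start = 0
    bins = df["km_bin"].to_numpy()
    for n, flag in runs:
        sub = df.iloc[start : start + n]
        if len(sub) >= 3:
            res = stats.linregress(sub["km_bin"], sub["mean_peak_date"])
            slope, p = float(res.slope), float(res.pvalue)
        else:
            slope, p = float("nan"), float("nan")
        seg_rows.append(
            dict(
                km_lo=int(bins[start]),
                km_hi=int(bins[start + n - 1]),
                direction="positive" if flag else "negative",
                slope=slope,
                p_value=p,
                n_bins=n,
            )
        )
        start += n
    return WaveProfile(profile=df, segments=pd.DataFrame(seg_rows))


def weekly_wave_profile(
    raster: PhenoRaster, day_range: tuple[int, int] = (60, 200)
) -> pd.DataFrame:
    """Median IRG per kilometre and week — the display form of the wave.

    Weeks are consecutive 7-day blocks of day-of-year starting at
    ``day_range[0]``; the median is over every (cell, day) in the block and
    km bin.
    """
    d0, d1 = day_range
    days = np.arange(d0, d1)
    week = (days - d0) // 7
    km_bin = np.floor(raster.x_km).astype(int)
    rows = []
    for w in np.unique(week):
        sel = days[week == w]
        # IRG for each cell and day of this week: (n_days, ny, nx)
        e = np.exp((raster.xmidS[None] - sel[:, None, None]) / raster.scalS[None])
        irg = e / (raster.scalS[None] * (1.0 + e) ** 2)
        for kb in np.unique(km_bin):
            vals = irg[:, :, km_bin == kb]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                rows.append(
                    dict(km_bin=int(kb), week=int(w), day_mid=float(sel.mean()),
                         median_irg=float(np.median(vals)))
                )
    return pd.DataFrame(rows)


def smooth_profile(x, y, frac: float = 0.3) -> np.ndarray:
    """Lowess smoother for display curves (weekly wave, penalty profiles)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out = lowess(y, x, frac=frac, return_sorted=False)
    return np.asarray(out)


def penalty_profile(raster: PhenoRaster, max_km: float | None = None) -> pd.DataFrame:
    """Mean loss-in-IRG foraging penalty per corridor quarter.

    Returns one row per quarter plus the last/first ratio as a DataFrame
    attribute ``last_over_first``; a ratio above 1 means mismatch costs
    more near the summer range, where green-up is rapid and fleeting.
    """
    length = max_km if max_km is not None else raster.corridor_length_km
    loss = raster.loss_grid()
    km = np.repeat(raster.x_km[None, :], raster.y_km.size, axis=0)
    ok = np.isfinite(loss) & (km <= length)
    quarter = np.minimum((km / (length / 4.0)).astype(int), 3)
    rows = []
    for q in range(4):
        vals = loss[ok & (quarter == q)]
        rows.append(
            dict(
                quarter=q + 1,
                km_lo=q * length / 4.0,
                km_hi=(q + 1) * length / 4.0,
                mean_loss_pct=float(vals.mean()) if vals.size else float("nan"),
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["last_over_first"] = float(
        out["mean_loss_pct"].iloc[3] / out["mean_loss_pct"].iloc[0]
    )
    return out
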