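"""End-to-end orchestration: config, staged pipeline, report bundle.

Every numeric constant of the analysis lives in :class:`RunConfig` —
stage code receives thresholds from it, never hard-codes them.  The
defaults are the analysis constants: 10.8 km/h speed filter, 7-day
compensation window, 3-day minimum stopover, motion-variance gate at
8,000 m^2/min, 99%/10% BBMM isopleths, 95% seasonal-range isopleth,
150-m grid.

``run_all`` executes simulate -> phenology -> clean/segment -> surf ->
stopovers -> classify -> summarize on synthetic data (or on tracks and a
phenology raster read from the configured paths), writing per-stage CSV
artifacts, a JSON report and a structured run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compensation as comp
from . import stopovers as stp
from . import surfing as srf
from . import synthetic as syn
from . import tracks as trk
from .phenology import PhenoRaster

log = logging.getLogger("greenwave")

__all__ = ["RunConfig", "RunReport", "validate_config", "run_all", "load_config"]

_PAPER_DEFAULTS = {
    "speed_filter_kmh": 10.8,
    "compensation_window_days": 7.0,
    "stopover_min_days": 3.0,
    "variance_gate": 8000.0,
    "corridor_isopleth": 0.99,
    "stopover_isopleth": 0.10,
    "range_isopleth": 0.95,
    "grid_m": 150.0,
}


@dataclass
class RunConfig:
    """All knobs of one analysis run."""

    # paths (optional: the simulate stage replaces them)
    tracks_dir: str | None = None
    phenology_path: str | None = None
    outdir: str = "greenwave_out"
    simulate: bool = True
    # thresholds — defaults are the analysis constants
    speed_filter_kmh: float = 10.8
    compensation_window_days: float = 7.0
    stopover_min_days: float = 3.0
    variance_gate: float = 8000.0
    corridor_isopleth: float = 0.99
    stopover_isopleth: float = 0.10
    range_isopleth: float = 0.95
    grid_m: float = 150.0
    location_error_m: float = 20.0
    max_lag_hours: float = 8.0
    # synthetic cohort
    n_agents: int = 60
    departure_spread_days: float = 100.0
    n_days: int = 170
    landscape: dict = field(default_factory=dict)  # LandscapeSpec overrides
    seed: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ok, violations = validate_config(d)
        if not ok:
            raise ValueError("invalid config: " + "; ".join(violations))
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def validate_config(d: dict) -> tuple[bool, list[str]]:
    """Type/range checks plus a list of deviations from the default
    analysis constants.  Unknown keys raise immediately."""
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(d) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    violations: list[str] = []
    positive = [
        "speed_filter_kmh",
        "stopover_min_days",
        "variance_gate",
        "grid_m",
        "n_agents",
        "n_days",
        "departure_spread_days",
    ]
    for k in positive:
        if k in d and not (isinstance(d[k], (int, float)) and d[k] > 0):
            violations.append(f"{k} must be positive, got {d[k]!r}")
    if "compensation_window_days" in d and d["compensation_window_days"] < 0:
        violations.append("compensation_window_days must be >= 0")
    for k in ("corridor_isopleth", "stopover_isopleth", "range_isopleth"):
        if k in d and not (0 < d[k] <= 1):
            violations.append(f"{k} must be a fraction in (0, 1], got {d[k]!r}")
    deviations = [
        f"{k}: {d[k]} (default {v})"
        for k, v in _PAPER_DEFAULTS.items()
        if k in d and d[k] != v
    ]
    for msg in deviations:
        log.info("config deviates from analysis default — %s", msg)
    return (not violations), violations + deviations


@dataclass
class RunReport:
    """Artifacts of one full pipeline run."""

    records: pd.DataFrame
    summary: dict
    ordinal_fit: comp.OrdinalFit | None
    wave: srf.WaveProfile
    penalty: pd.DataFrame
    landscape: PhenoRaster
    outdir: Path
    dropped: dict


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:12]


def _load_tracks(cfg: RunConfig) -> tuple[list[trk.Track], pd.DataFrame]:
    paths = sorted(Path(cfg.tracks_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no track CSVs under {cfg.tracks_dir}")
    tracks = [trk.Track.from_movebank_csv(p) for p in paths]
    cov = pd.DataFrame(
        {"animal_year": [t.animal_year for t in tracks],
         "year": [t.year for t in tracks]}
    )
    return tracks, cov


def run_all(cfg: RunConfig, write: bool = True) -> RunReport:
    """Execute every stage; halt with the stage name on failure."""
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if cfg.simulate:
            spec = syn.LandscapeSpec(**{"seed": cfg.seed, **cfg.landscape})
            landscape = syn.make_landscape(spec)
            tracks, cov = syn.make_cohort(
                landscape,
                cfg.n_agents,
                departures=cfg.departure_spread_days,
                seed=cfg.seed + 1,
                n_days=cfg.n_days,
            )
        else:
            landscape = PhenoRaster.from_netcdf(cfg.phenology_path)
            tracks, cov = _load_tracks(cfg)
        log.info("stage=simulate n_tracks=%d", len(tracks))

        dropped = {"speed_filter": 0, "missing_phenology": 0, "variance_gate": 0,
                   "resident": 0}
        rows = []
        for track in tracks:
            stage = f"clean/segment [{track.animal_year}]"
            clean, removed = trk.speed_filter(track, cfg.speed_filter_kmh)
            dropped["speed_filter"] += removed
            window = trk.segment_migration(clean)
            if window.resident:
                dropped["resident"] += 1
                continue

            stage = f"ranges [{track.animal_year}]"
            df = clean.df
            winter_pts = df[df["t"] < window.start_date][["x", "y"]].to_numpy()
            summer_pts = df[df["t"] > window.end_date][["x", "y"]].to_numpy()
            winter = trk.seasonal_range(
                winter_pts, "winter", landscape, cfg.range_isopleth, cfg.grid_m
            )
            summer = trk.seasonal_range(
                summer_pts, "summer", landscape, cfg.range_isopleth, cfg.grid_m
            )

            stage = f"surf [{track.animal_year}]"
            rec, n_drop = srf.days_from_peak(clean, landscape)
            dropped["missing_phenology"] += n_drop
            profile = srf.aggregate_dfp(rec, clean.animal_year, window)
            dfp_start = srf.range_mismatch(window, winter)
            dfp_end = srf.range_mismatch(window, summer)

            stage = f"stopovers [{track.animal_year}]"
            mig = clean.df[
                (clean.df["t"] >= window.start_date)
                & (clean.df["t"] <= window.end_date)
            ].reset_index(drop=True)
            mig_track = dataclasses.replace(clean, df=mig)
            sigma2, _ = stp.estimate_motion_variance(
                mig_track, cfg.location_error_m, cfg.max_lag_hours
            )
            gate_ok = stp.variance_gate(sigma2, cfg.variance_gate)
            stop_days = np.nan
            if gate_ok:
                bb = stp.bbmm_ud(
                    mig_track, sigma2, cfg.grid_m, cfg.location_error_m,
                    cfg.max_lag_hours,
                )
                stops = stp.stopover_days(
                    mig_track, bb, cfg.stopover_isopleth, cfg.stopover_min_days
                )
                stop_days = stops.total_days
            else:
                dropped["variance_gate"] += 1

            rows.append(
                dict(
                    animal_year=clean.animal_year,
                    year=clean.year,
                    start_date=window.start_date,
                    end_date=window.end_date,
                    duration=window.duration,
                    distance_km=window.distance_km,
                    movement_rate=trk.movement_rate(window),
                    mean_dfp=profile.mean_dfp,
                    dfp_start=dfp_start,
                    dfp_end=dfp_end,
                    motion_variance=sigma2,
                    gate_pass=gate_ok,
                    stopover_days=stop_days,
                    removed_fixes=removed,
                )
            )
        records = pd.DataFrame(rows)
        log.info(
            "stage=per-animal n_records=%d dropped=%s", len(records), dropped
        )

        stage = "classify"
        records["standardized_start"] = comp.standardize_start(records)
        records["timing_class"] = comp.classify_timing(
            records["standardized_start"].to_numpy()
        )
        records["comp_class"] = [
            comp.classify_compensation(s, e, cfg.compensation_window_days)
            for s, e in zip(records["dfp_start"], records["dfp_end"])
        ]

        stage = "summarize"
        summary = comp.cohort_summary(records)
        ordinal_fit = None
        if records["comp_class"].nunique() >= 2:
            ordinal_fit = comp.fit_ordinal(
                records["comp_class"], records["dfp_start"].abs()
            )
        wave = srf.wave_propagation(landscape)
        penalty = srf.penalty_profile(landscape)
        report = RunReport(
            records=records,
            summary=summary,
            ordinal_fit=ordinal_fit,
            wave=wave,
            penalty=penalty,
            landscape=landscape,
            outdir=outdir,
            dropped=dropped,
        )
        if write:
            stage = "write"
            _write_bundle(report, cfg)
        return report
    except Exception as err:
        log.error("pipeline halted at stage=%s: %s", stage, err)
        raise RuntimeError(f"stage failure at {stage!r}: {err}") from err


def _write_bundle(report: RunReport, cfg: RunConfig) -> None:
    out = report.outdir
    report.records.to_csv(out / "records.csv", index=False)
    report.summary["per_class"].to_csv(out / "per_class.csv", index=False)
    report.wave.profile.to_csv(out / "wave_profile.csv", index=False)
    report.wave.segments.to_csv(out / "wave_segments.csv", index=False)
    report.penalty.to_csv(out / "penalty_quarters.csv", index=False)
    report.landscape.to_netcdf(out / "landscape.nc")
    blob = {
        "config": cfg.to_dict(),
        "n_records": int(len(report.records)),
        "dropped": report.dropped,
        "records_hash": _hash_df(report.records),
        "sd_start": report.summary["sd_start"],
        "sd_end": report.summary["sd_end"],
        "paired_t": report.summary["paired_t"],
        "comp_class_counts": report.records["comp_class"]
        .value_counts()
        .to_dict(),
        "timing_class_counts": report.records["timing_class"]
        .value_counts()
        .to_dict(),
        "penalty_last_over_first": report.penalty.attrs["last_over_first"],
    }
    if report.ordinal_fit is not None:
        orr = comp.odds_ratio(report.ordinal_fit)
        blob["ordinal"] = {
            "beta": report.ordinal_fit.beta,
            "se": report.ordinal_fit.se,
            "ci95": list(report.ordinal_fit.ci95),
            "cutpoints": report.ordinal_fit.cutpoints.tolist(),
            "loglik": report.ordinal_fit.loglik,
            "odds_ratio": orr["odds_ratio"],
            "odds_ratio_ci95": list(orr["ci95"]),
        }
    with open(out / "report.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)
    if report.ordinal_fit is not None:
        x = np.linspace(0.0, 45.0, 91)
        report.ordinal_fit.predict_probs(x).rename_axis("abs_dfp_start").to_csv(
            out / "comp_probability_curves.csv"
        )

    from .plots import plot_comp_probability, plot_mismatch_by_class, plot_wave

    plot_wave(report.wave, out / "fig_wave_propagation.png")
    plot_mismatch_by_class(report.records, out / "fig_mismatch_by_class.png")
    if report.ordinal_fit is not None:
        plot_comp_probability(report.ordinal_fit, out / "fig_comp_probability.png")
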