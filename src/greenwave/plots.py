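"""Display figures for the report bundle.

Static matplotlib renderings of the analysis products: the green-wave
propagation profile, per-class mismatch at the start and end of
migration, and the fitted probability of each compensation class against
starting mismatch.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .compensation import OrdinalFit, TIMING_CLASSES
from .surfing import WaveProfile

__all__ = ["plot_wave", "plot_mismatch_by_class", "plot_comp_probability"]

_CLASS_COLORS = {"early": "#7b3294", "mid": "#008837", "late": "#e66101"}


def plot_wave(wave: WaveProfile, path) -> None:
    """Mean date of peak IRG along the corridor, dotted where the wave
    propagates backwards."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    prof = wave.profile
    for _, seg in wave.segments.iterrows():
        sub = prof[(prof["km_bin"] >= seg["km_lo"]) & (prof["km_bin"] <= seg["km_hi"])]
        style = "-" if seg["direction"] == "positive" else ":"
        ax.plot(sub["km_bin"], sub["mean_peak_date"], style, color="forestgreen",
                lw=2)
    ax.set_xlabel("distance along migration corridor (km)")
    ax.set_ylabel("mean date of peak IRG (day of year)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mismatch_by_class(records: pd.DataFrame, path) -> None:
    """Days-From-Peak at the start and end of migration per timing class."""
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2), sharey=True)
    for ax, tc in zip(axes, TIMING_CLASSES):
        sub = records[records["timing_class"] == tc]
        if len(sub):
            ax.boxplot(
                [sub["dfp_start"], sub["dfp_end"]],
                tick_labels=["start", "end"],
                boxprops=dict(color=_CLASS_COLORS[tc]),
                medianprops=dict(color="black"),
            )
        ax.axhline(0.0, ls="--", c="grey", lw=1)
        ax.set_title(f"{tc} (n={len(sub)})")
    axes[0].set_ylabel("Days-From-Peak")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_comp_probability(fit: OrdinalFit, path, x_max: float = 45.0) -> None:
    """Fitted per-class probability curves against |starting mismatch|."""
    x = np.linspace(0.0, x_max, 181)
    probs = fit.predict_probs(x)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for cls in probs.columns:
        ax.plot(x, probs[cls], label=cls, lw=2)
    ax.set_xlabel("|Days-From-Peak| at start of migration")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
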