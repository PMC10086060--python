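"""Compensation for phenological mismatch: timing classes, compensator
classes, and the ordinal model of full-compensation probability.

An animal-year's mismatch is summarised by its Days-From-Peak at the
start (winter range) and end (summer range) of spring migration.  With a
7-day tolerance window the four outcomes are:

* **perfect surfer** — started within 7 days of peak and stayed within 7;
* **full compensator** — started more than 7 days off but ended closer to
  peak than it started;
* **partial compensator** — started more than 7 days off and ended about
  as far off as it started (within 7 days of the starting magnitude);
* **non-compensator** — drifted further from peak than it started.

The verbal rules overlap (improving from 20 to 15 days off is both
"closer" and "within 7 of the start"), so classification applies a fixed
precedence: perfect, then full, then partial, then non.

The probability of full compensation as a function of absolute starting
mismatch is modelled with a cumulative-logit (proportional-odds)
regression over the ordering non < perfect < partial < full, read as
increasing behavioral adjustment; exp(beta) is the per-day odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "COMP_CLASSES",
    "TIMING_CLASSES",
    "CompensationRecord",
    "OrdinalFit",
    "OrdinalCompensationModel",
    "standardize_start",
    "classify_timing",
    "classify_compensation",
    "fit_ordinal",
    "odds_ratio",
    "cohort_summary",
]

COMP_CLASSES = ("non", "perfect", "partial", "full")  # ordinal, increasing adjustment
TIMING_CLASSES = ("early", "mid", "late")
COMPENSATION_WINDOW_DAYS = 7.0


@dataclass
class CompensationRecord:
    """Timing and compensation outcome of one animal-year."""

    animal_year: str
    standardized_start: float
    timing_class: str
    dfp_start: float
    dfp_end: float
    comp_class: str


def standardize_start(starts: pd.DataFrame) -> pd.Series:
    """Start date minus the annual median start date.

    ``starts`` needs columns ``year`` and ``start_date``; the result keeps
    the input index so it can be assigned straight back to a cohort table.
    """
    med = starts.groupby("year")["start_date"].transform("median")
    return starts["start_date"] - med


def classify_timing(standardized_starts) -> np.ndarray:
    """Early / mid / late migrant classes from pooled quartiles.

    Early: <= 25% quantile; late: >= 75% quantile; mid otherwise.  The
    quantiles use linear interpolation (the type-7 definition).  A value
    satisfying both boundary rules (possible under heavy ties) is early —
    the first rule wins.
    """
    v = np.asarray(standardized_starts, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 animal-years for quartile classes")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    out = np.where(v <= q1, "early", np.where(v >= q3, "late", "mid"))
    return out


def classify_compensation(
    dfp_start: float,
    dfp_end: float,
    window: float = COMPENSATION_WINDOW_DAYS,
) -> str:
    """Assign the compensation class for one animal-year.

    Precedence perfect -> full -> partial -> non over the (|start|, |end|)
    plane; total and single-valued for any finite pair.
    """
    s, e = abs(float(dfp_start)), abs(float(dfp_end))
    if not (np.isfinite(s) and np.isfinite(e)):
        raise ValueError("start and end mismatches must be finite")
    if s <= window and e <= window:
        return "perfect"
    if s > window and e < s:
        return "full"
    if s > window and abs(e - s) <= window:
        return "partial"
    return "non"


@dataclass
class OrdinalFit:
    """Proportional-odds fit summary for one predictor."""

    beta: float
    se: float
    ci95: tuple[float, float]
    cutpoints: np.ndarray
    loglik: float
    predictor: str
    converged: bool
    separation_flag: bool
    classes: tuple = COMP_CLASSES
    _results: object = None

    def predict_probs(self, x) -> pd.DataFrame:
        """Per-class probabilities at predictor values ``x`` (rows sum to 1)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        eta = self.beta * x
        cum = 1.0 / (1.0 + np.exp(-(self.cutpoints[None, :] - eta[:, None])))
        cum = np.hstack([np.zeros((x.size, 1)), cum, np.ones((x.size, 1))])
        probs = np.diff(cum, axis=1)
        return pd.DataFrame(probs, columns=list(self.classes), index=x)

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Proportional-odds model of compensation class",
            f"  ordering : {' < '.join(self.classes)}",
            f"  predictor: {self.predictor}",
            f"  beta     : {self.beta:.4f} (SE {self.se:.4f})",
            f"  95% CI   : [{lo:.4f}, {hi:.4f}]",
            f"  odds ratio per unit: {np.exp(self.beta):.4f}",
            f"  cutpoints: {np.array2string(self.cutpoints, precision=3)}",
            f"  loglik   : {self.loglik:.3f}",
        ]
        if self.separation_flag:
            lines.append("  WARNING: possible complete separation (diverging beta)")
        return "\n".join(lines)


class OrdinalCompensationModel:
    """Cumulative-logit model of compensation class versus one predictor.

    Endog is the compensation class (ordered non < perfect < partial <
    full), exog a single numeric predictor — absolute Days-From-Peak at the
    start of migration, or age.  ``fit`` wraps a maximum-likelihood
    proportional-odds fit and reports the slope with its Wald 95% CI.
    """

    def __init__(self, comp_class, predictor, predictor_name: str = "abs_dfp_start"):
        observed = set(np.asarray(comp_class, dtype=object))
        if not observed <= set(COMP_CLASSES):
            raise ValueError(f"comp_class values must be in {COMP_CLASSES}")
        # the cumulative-logit likelihood is undefined for empty levels:
        # fit over the observed levels, keeping the global ordering
        self.classes = tuple(c for c in COMP_CLASSES if c in observed)
        y = pd.Categorical(comp_class, categories=list(self.classes), ordered=True)
        x = np.asarray(predictor, dtype=float)
        if len(y) != x.size:
            raise ValueError("outcome and predictor lengths differ")
        if pd.Series(y).nunique() < 2:
            raise ValueError("need at least 2 outcome levels present")
        self.endog = y
        self.exog = pd.DataFrame({predictor_name: x})
        self.predictor_name = predictor_name

    def fit(self) -> OrdinalFit:
        model = OrderedModel(
            pd.Series(self.endog), self.exog, distr="logit"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=500, disp=False)
        beta = float(res.params.iloc[0])
        se = float(res.bse.iloc[0])
        ci = res.conf_int().iloc[0]
        cut = model.transform_threshold_params(res.params.to_numpy())
        # drop the +/- inf sentinels statsmodels includes
        cutpoints = np.asarray(cut[1:-1], dtype=float)
        separation = (not np.isfinite(se)) or abs(beta) > 30.0 or se > 1e3
        if separation:
            warnings.warn("possible complete separation: beta diverging")
        return OrdinalFit(
            beta=beta,
            se=se,
            ci95=(float(ci.iloc[0]), float(ci.iloc[1])),
            cutpoints=cutpoints,
            loglik=float(res.llf),
            predictor=self.predictor_name,
            converged=bool(res.mle_retvals.get("converged", True)),
            separation_flag=bool(separation),
            classes=self.classes,
            _results=res,
        )


def fit_ordinal(comp_class, predictor, predictor_name: str = "abs_dfp_start") -> OrdinalFit:
    """Functional wrapper around :class:`OrdinalCompensationModel`."""
    return OrdinalCompensationModel(comp_class, predictor, predictor_name).fit()


def odds_ratio(fit: OrdinalFit) -> dict:
    """Per-unit odds ratio exp(beta) with its exp-transformed 95% CI."""
    lo, hi = fit.ci95
    return {
        "odds_ratio": float(np.exp(fit.beta)),
        "ci95": (float(np.exp(lo)), float(np.exp(hi))),
    }


def _mean_ci(v: np.ndarray) -> tuple[float, float]:
    """Normal-theory mean and 95% half-width (NaN half-width when n < 2)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        return (float(v.mean()) if v.size else float("nan"), float("nan"))
    return float(v.mean()), float(1.96 * v.std(ddof=1) / np.sqrt(v.size))


def z_test_mean_zero(v) -> tuple[float, float]:
    """Two-sided z-test of mean 0 using the sample SD."""
    v = np.asarray(v, dtype=float)
    if v.size < 2 or v.std(ddof=1) == 0:
        return float("nan"), float("nan")
    z = v.mean() / (v.std(ddof=1) / np.sqrt(v.size))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def cohort_summary(records: pd.DataFrame) -> dict:
    """Population statistics over a table of animal-year records.

    Expects columns ``timing_class``, ``dfp_start``, ``dfp_end`` and
    optionally ``movement_rate`` and ``stopover_days``.  Returns per-class
    means with 95% CIs, the paired t and Wilcoxon signed-rank tests of
    |DFP| start versus end, one-way ANOVAs across timing classes, and
    two-sided z-tests of the start/end mismatches against zero.
    """
    out: dict = {"n": len(records)}
    per_class = []
    for tc in TIMING_CLASSES:
        sub = records[records["timing_class"] == tc]
        row: dict = {"timing_class": tc, "n": len(sub)}
        for col in ("dfp_start", "dfp_end", "movement_rate", "stopover_days"):
            if col in sub.columns and len(sub):
                m, hw = _mean_ci(sub[col].to_numpy())
                row[f"mean_{col}"], row[f"ci95_{col}"] = m, hw
        per_class.append(row)
    out["per_class"] = pd.DataFrame(per_class)

    s = records["dfp_start"].abs().to_numpy()
    e = records["dfp_end"].abs().to_numpy()
    diff = e - s
    if np.allclose(diff, 0):  # identical columns: no change, not undefined
        out["paired_t"] = {"t": 0.0, "p": 1.0, "df": int(s.size - 1)}
    else:
        t_res = stats.ttest_rel(e, s)
        out["paired_t"] = {"t": float(t_res.statistic), "p": float(t_res.pvalue),
                           "df": int(s.size - 1)}
    if np.allclose(diff, 0):
        out["wilcoxon"] = {"w": float("nan"), "p": 1.0}
    else:
        w_res = stats.wilcoxon(e, s)
        out["wilcoxon"] = {"w": float(w_res.statistic), "p": float(w_res.pvalue)}

    for col in ("movement_rate", "stopover_days", "dfp_start", "dfp_end"):
        if col not in records.columns:
            continue
        groups = [
            records.loc[records["timing_class"] == tc, col].dropna().to_numpy()
            for tc in TIMING_CLASSES
        ]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) >= 2:
            f_res = stats.f_oneway(*groups)
            out[f"anova_{col}"] = {"F": float(f_res.statistic),
                                   "p": float(f_res.pvalue)}
    z, p = z_test_mean_zero(records["dfp_start"].to_numpy())
    out["ztest_start"] = {"z": z, "p": p}
    z, p = z_test_mean_zero(records["dfp_end"].to_numpy())
    out["ztest_end"] = {"z": z, "p": p}
    out["sd_start"] = float(records["dfp_start"].std(ddof=1))
    out["sd_end"] = float(records["dfp_end"].std(ddof=1))
    return out
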