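"""Timing and compensation classification, the proportional-odds model,
and the cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenwave import (
    OrdinalFit,
    classify_compensation,
    classify_timing,
    cohort_summary,
    fit_ordinal,
    odds_ratio,
    standardize_start,
)
from greenwave.compensation import COMP_CLASSES


class TestStandardizeStart:
    def test_single_year_median_centred(self):
        df = pd.DataFrame({"year": 2015, "start_date": [100.0, 110.0, 120.0]})
        assert np.allclose(standardize_start(df), [-10.0, 0.0, 10.0])

    def test_single_animal_year_is_zero(self):
        df = pd.DataFrame({"year": [2015], "start_date": [137.0]})
        assert standardize_start(df).iloc[0] == 0.0

    def test_multi_year_matches_groupby_oracle(self, rng):
        df = pd.DataFrame(
            {
                "year": rng.choice([2011, 2012, 2013], 60),
                "start_date": rng.uniform(80, 160, 60),
            }
        )
        out = standardize_start(df)
        for yr, grp in df.groupby("year"):
            expected = grp["start_date"] - grp["start_date"].median()
            assert np.allclose(out[grp.index], expected)


class TestClassifyTiming:
    def test_enumeration_against_quantile_formula(self):
        v = np.arange(1.0, 9.0)  # 1..8
        q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7: 2.75, 6.25
        classes = classify_timing(v)
        for val, cls in zip(v, classes):
            if val <= q1:
                assert cls == "early"
            elif val >= q3:
                assert cls == "late"
            else:
                assert cls == "mid"
        assert set(classes) == {"early", "mid", "late"}

    def test_all_equal_values_are_early_by_tie_rule(self):
        assert list(classify_timing(np.zeros(6))) == ["early"] * 6

    def test_partition_totality(self, rng):
        v = rng.normal(0, 20, 151)
        classes = classify_timing(v)
        assert len(classes) == 151
        assert set(classes) <= {"early", "mid", "late"}
        assert all((classes == c).sum() > 0 for c in ("early", "mid", "late"))

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            classify_timing([1.0, 2.0, 3.0])


def _rule_table(s, e, w=7.0):
    """Independent restatement of the class rules for the oracle."""
    s, e = abs(s), abs(e)
    started_within = s <= w
    ended_within = e <= w
    if started_within and ended_within:
        return "perfect"
    if not started_within:
        if e < s:
            return "full"
        if e - s <= w:  # e >= s here, so |e - s| == e - s
            return "partial"
        return "non"
    return "non"  # started within 7 but drifted out


class TestClassifyCompensation:
    @pytest.mark.parametrize(
        "s,e,expected",
        [
            (-30.0, 4.0, "full"),  # early migrant that caught the wave
            (0.0, 0.0, "perfect"),
            (3.0, 20.0, "non"),  # started on the wave, drifted off it
            (20.0, 15.0, "full"),  # closer AND within 7 of start: full wins
            (10.0, 16.0, "partial"),
            (10.0, 18.0, "non"),
            (-8.0, 8.0, "partial"),  # |end| == |start|: not closer, within 7
        ],
    )
    def test_known_cases(self, s, e, expected):
        assert classify_compensation(s, e) == expected

    def test_exhaustive_grid_matches_oracle(self):
        grid = np.arange(-45.0, 45.5, 0.5)
        for s in grid:
            for e in grid:
                got = classify_compensation(s, e)
                assert got == _rule_table(s, e), (s, e)
                assert got in COMP_CLASSES

    @given(
        st.floats(-200, 200, allow_nan=False),
        st.floats(-200, 200, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_total_and_single_valued(self, s, e):
        assert classify_compensation(s, e) in COMP_CLASSES

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_compensation(np.nan, 0.0)


def simulate_proportional_odds(beta, cutpoints, n, rng):
    """Draw classes from the exact cumulative-logit model."""
    x = rng.uniform(0.0, 45.0, n)
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(cutpoints)[None, :] - beta * x[:, None])))
    cum = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
    p = np.diff(cum, axis=1)
    u = rng.uniform(size=n)
    idx = (u[:, None] >= np.cumsum(p, axis=1)).sum(axis=1)
    return x, np.asarray(COMP_CLASSES)[idx]


class TestOrdinalModel:
    def test_monte_carlo_recovery_with_ci_coverage(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 100
        for _ in range(reps):
            x, y = simulate_proportional_odds(0.19, [0.5, 1.2, 2.0], 5000, rng)
            fit = fit_ordinal(y, x)
            half = 0.5 * (fit.ci95[1] - fit.ci95[0])
            hits += abs(fit.beta - 0.19) <= half
        assert hits >= 90

    def test_permuted_predictor_estimates_null(self):
        rng = np.random.default_rng(11)
        x, y = simulate_proportional_odds(0.19, [0.5, 1.2, 2.0], 2000, rng)
        fit = fit_ordinal(y, rng.permutation(x))
        assert abs(fit.beta) < 2.0 * fit.se

    def test_loglik_beats_intercept_only_null(self):
        rng = np.random.default_rng(13)
        x, y = simulate_proportional_odds(0.19, [0.5, 1.2, 2.0], 1000, rng)
        fit = fit_ordinal(y, x)
        # beta = 0 with cutpoints refit: MLE is the empirical class frequencies
        counts = pd.Series(y).value_counts()
        null_ll = float((counts * np.log(counts / counts.sum())).sum())
        assert fit.loglik >= null_ll

    def test_probability_curves_sum_to_one(self):
        rng = np.random.default_rng(17)
        x, y = simulate_proportional_odds(0.1, [0.3, 1.0, 1.8], 800, rng)
        fit = fit_ordinal(y, x)
        probs = fit.predict_probs(np.linspace(0, 45, 20))
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs.to_numpy() >= 0).all()

    def test_requires_outcome_variation(self):
        with pytest.raises(ValueError):
            fit_ordinal(["full"] * 10, np.arange(10.0))


class TestOddsRatio:
    def test_printed_coefficient_reproduces_printed_ratio(self):
        fit = OrdinalFit(0.19, 0.01, (0.15, 0.24), np.array([0.0]), 0.0, "x", True, False)
        assert round(odds_ratio(fit)["odds_ratio"], 2) == 1.21

    def test_null_beta_gives_unit_ratio(self):
        fit = OrdinalFit(0.0, 0.01, (-0.1, 0.1), np.array([0.0]), 0.0, "x", True, False)
        assert odds_ratio(fit)["odds_ratio"] == 1.0

    def test_log_two_doubles_odds(self):
        fit = OrdinalFit(np.log(2.0), 0.01, (0.5, 0.9), np.array([0.0]), 0.0,
                         "x", True, False)
        out = odds_ratio(fit)
        assert out["odds_ratio"] == pytest.approx(2.0)
        assert out["ci95"][0] == pytest.approx(np.exp(0.5))


def _records(n=40, seed=0):
    rng = np.random.default_rng(seed)
    start = rng.uniform(-35, 35, n)
    end = rng.normal(0, 3, n)
    return pd.DataFrame(
        {
            "timing_class": classify_timing(start),
            "dfp_start": start,
            "dfp_end": end,
            "movement_rate": rng.uniform(2, 6, n),
            "stopover_days": rng.uniform(0, 12, n),
        }
    )


class TestCohortSummary:
    def test_identical_columns_give_null_paired_tests(self):
        rec = _records()
        rec["dfp_end"] = rec["dfp_start"]
        out = cohort_summary(rec)
        assert out["paired_t"]["t"] == 0.0
        assert out["paired_t"]["p"] == 1.0
        assert out["wilcoxon"]["p"] == 1.0

    def test_textbook_fixture_matches_hand_computation(self):
        # two timing classes of three, movement rates computed by hand
        rec = pd.DataFrame(
            {
                "timing_class": ["early"] * 3 + ["late"] * 3,
                "dfp_start": [-20.0, -18.0, -22.0, 15.0, 17.0, 13.0],
                "dfp_end": [-1.0, 2.0, 0.0, 3.0, 5.0, 4.0],
                "movement_rate": [1.0, 2.0, 3.0, 2.0, 4.0, 6.0],
            }
        )
        out = cohort_summary(rec)
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        grand = np.concatenate([a, b]).mean()
        ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ss_between / 1.0) / (ss_within / 4.0)
        assert out["anova_movement_rate"]["F"] == pytest.approx(f_oracle)
        early = out["per_class"].set_index("timing_class").loc["early"]
        assert early["mean_dfp_start"] == pytest.approx(-20.0)
        assert early["ci95_dfp_start"] == pytest.approx(1.96 * 2.0 / np.sqrt(3))

    def test_zero_mean_mismatch_z_test_null(self):
        rec = _records()
        rec["dfp_start"] = np.tile([-1.0, 1.0], 20)
        out = cohort_summary(rec)
        assert out["ztest_start"]["z"] == pytest.approx(0.0)
        assert out["ztest_start"]["p"] == pytest.approx(1.0)

    def test_paired_t_detects_compensation(self):
        out = cohort_summary(_records())
        # |end| systematically below |start|: strongly negative paired t
        assert out["paired_t"]["t"] < -5.0
        assert out["paired_t"]["p"] < 1e-5
        assert out["sd_end"] < out["sd_start"]
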