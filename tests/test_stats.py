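"""Discrimination-statistics tests: group comparisons, AUROC and its
Mann-Whitney identity, DeLong intervals and paired test, odds ratios, and
logistic regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msofa.stats import (
    bootstrap_auc_ci,
    contingency_odds_ratio,
    delong_ci,
    delong_paired_test,
    empirical_auroc,
    fit_logistic,
    group_compare_categorical,
    group_compare_continuous,
)


def brute_force_auroc(scores, outcomes):
    """All-pairs concordance oracle: P(case > control) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes)
    pos, neg = scores[outcomes == 1], scores[outcomes == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestGroupCompareContinuous:
    def test_identical_groups_p_one(self):
        values = [3.0, 3.0, 3.0, 3.0]
        cmp = group_compare_continuous(values, [0, 0, 1, 1], method="t")
        assert cmp.p_value == 1.0 and cmp.statistic == 0.0

    def test_complete_separation(self):
        cmp = group_compare_continuous(
            [0, 0, 0, 10, 10, 10.001], [0, 0, 0, 1, 1, 1], method="t")
        died = cmp.group_summary["died"]["mean"]
        surv = cmp.group_summary["survived"]["mean"]
        assert died - surv == pytest.approx(10, abs=0.01)
        assert cmp.p_value < 1e-6

    def test_auto_switches_to_mann_whitney_on_skew(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.lognormal(0, 2, 60), rng.lognormal(0.2, 2, 60)])
        outcomes = np.array([0] * 60 + [1] * 60)
        cmp = group_compare_continuous(values, outcomes, method="auto")
        assert cmp.test == "mann_whitney"
        assert "shapiro" in cmp.note

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="died"):
            group_compare_continuous([1.0, 2.0], [0, 0])

    def test_pooled_variant_available(self):
        cmp = group_compare_continuous([1, 2, 3, 4.0], [0, 0, 1, 1],
                                       method="t", equal_var=True)
        assert 0 <= cmp.p_value <= 1


class TestGroupCompareCategorical:
    def test_perfect_independence(self):
        cmp = group_compare_categorical([[10, 10], [10, 10]])
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_ventilation_2x2_counts(self):
        # survivors: 47 ventilated / 16 not; non-survivors: 53 / 2
        table = np.array([[47, 16], [53, 2]])
        cmp = group_compare_categorical(table)
        # Pearson formula by hand: n(ad-bc)^2 / (row1 row2 col1 col2)
        n = table.sum()
        expected = n * (47 * 2 - 16 * 53) ** 2 / (63 * 55 * 100 * 18)
        assert cmp.statistic == pytest.approx(expected)
        assert cmp.p_value < 0.05
        assert cmp.p_value == pytest.approx(0.001, abs=5e-4)

    def test_empty_column_dropped_with_note(self):
        cmp = group_compare_categorical([[5, 0, 7], [3, 0, 9]])
        assert "dropped" in cmp.note

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            group_compare_categorical([[0, 0], [0, 0]])


class TestOddsRatio:
    def test_vasopressor_mortality_example(self):
        or_, lo, hi, corrected = contingency_odds_ratio([[24, 4], [31, 59]])
        assert or_ == pytest.approx(24 * 59 / (4 * 31), rel=1e-12)
        assert or_ == pytest.approx(11.42, abs=0.01)
        assert lo < or_ < hi and not corrected

    def test_symmetric_table_is_one(self):
        or_, lo, hi, _ = contingency_odds_ratio([[1, 1], [1, 1]])
        assert or_ == 1.0 and lo < 1 < hi

    def test_zero_cell_corrected(self):
        or_, lo, hi, corrected = contingency_odds_ratio([[5, 0], [3, 7]])
        assert corrected and math.isfinite(or_) and math.isfinite(hi)


class TestEmpiricalAuroc:
    @pytest.mark.parametrize(
        "scores, outcomes, expected",
        [
            ([3, 5, 1, 2], [1, 1, 0, 0], 1.0),       # perfect separation
            ([2, 2, 2, 2], [1, 1, 0, 0], 0.5),       # all ties
            ([2, 1, 1, 3], [1, 1, 0, 0], 0.375),     # (1 + 0.5)/4 pairs
        ],
    )
    def test_examples(self, scores, outcomes, expected):
        assert empirical_auroc(scores, outcomes) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auroc([1, 2], [1, 1])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=80)
        outcomes = rng.integers(0, 2, 80)
        base = empirical_auroc(scores, outcomes)
        for transform in (np.exp, np.tanh, lambda s: 3 * s + 7, np.cbrt):
            assert empirical_auroc(transform(scores), outcomes) == pytest.approx(base)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.integers(0, 8, n).astype(float)  # many ties
        outcomes = rng.integers(0, 2, n)
        if len(np.unique(outcomes)) < 2:
            outcomes[0], outcomes[-1] = 0, 1
        assert empirical_auroc(scores, outcomes) == pytest.approx(
            brute_force_auroc(scores, outcomes), abs=1e-12)


# frozen independent oracle (R pROC, DeLong method) on the fixture below
_PROC_AUC_A = 0.8976982097
_PROC_CI_A = (0.8062048109, 0.9891916085)
_PROC_AUC_B = 0.6061381074
_PROC_CI_B = (0.4279621129, 0.7843141020)
_PROC_PAIRED_P = 0.0063163441


def _delong_fixture():
    rng = np.random.default_rng(42)
    n = 40
    y = rng.integers(0, 2, n)
    a = np.round(y * 1.0 + rng.normal(0, 1, n), 3)
    b = np.round(y * 0.5 + rng.normal(0, 1, n), 3)
    return y.astype(int), a, b


class TestDeLong:
    def test_ci_matches_reference_implementation(self):
        y, a, b = _delong_fixture()
        ra = delong_ci(a, y)
        assert ra.auc == pytest.approx(_PROC_AUC_A, abs=1e-9)
        assert ra.ci_low == pytest.approx(_PROC_CI_A[0], abs=1e-9)
        assert ra.ci_high == pytest.approx(_PROC_CI_A[1], abs=1e-9)
        rb = delong_ci(b, y)
        assert rb.auc == pytest.approx(_PROC_AUC_B, abs=1e-9)
        assert rb.ci_low == pytest.approx(_PROC_CI_B[0], abs=1e-9)
        assert rb.ci_high == pytest.approx(_PROC_CI_B[1], abs=1e-9)

    def test_paired_test_matches_reference_implementation(self):
        y, a, b = _delong_fixture()
        auc_a, auc_b, p = delong_paired_test(a, b, y)
        assert p == pytest.approx(_PROC_PAIRED_P, abs=1e-9)

    def test_perfect_separation_clips_to_one(self):
        y = np.array([0] * 50 + [1] * 50)
        scores = y * 10.0
        res = delong_ci(scores, y)
        assert res.auc == 1.0 and res.ci_high == 1.0

    def test_null_ci_contains_half(self):
        # two interleaved classes of 50 with no score-outcome association
        scores = np.tile([1.0, 2.0], 50)
        y = np.array([0, 1, 1, 0] * 25)
        res = delong_ci(scores, y)
        assert res.ci_low < 0.5 < res.ci_high

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(9)
        widths = []
        for n in (50, 200, 800):
            y = np.array([0, 1] * (n // 2))
            scores = y * 0.9539 + rng.normal(0, 1, n)  # true AUC 0.75
            res = delong_ci(scores, y)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_degenerate_class_sizes_recommend_bootstrap(self):
        with pytest.raises(ValueError, match="bootstrap"):
            delong_ci([1.0, 2.0, 3.0], [1, 0, 0])

    def test_identical_scores_give_p_one(self):
        y, a, _ = _delong_fixture()
        _, _, p = delong_paired_test(a, a, y)
        assert p == 1.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2, 3], [1, 2], [1, 0, 1])

    def test_power_against_noise_score(self):
        rng = np.random.default_rng(13)
        y = np.array([0] * 63 + [1] * 55)
        perfect = y + rng.normal(0, 1e-6, 118)
        noise = rng.normal(0, 1, 118)
        _, _, p = delong_paired_test(perfect, noise, y)
        assert p < 0.05


class TestBootstrapCI:
    def test_contains_point_estimate_and_is_seeded(self):
        y, a, _ = _delong_fixture()
        r1 = bootstrap_auc_ci(a, y, seed=3, n_boot=500)
        r2 = bootstrap_auc_ci(a, y, seed=3, n_boot=500)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high


class TestLogistic:
    def test_null_recovery(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=10_000)
        y = rng.integers(0, 2, 10_000)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.converged and not fit.separation
        assert abs(fit.params["x"]) < 0.1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=10_000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        y = (rng.random(10_000) < p).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.params["const"] == pytest.approx(-1.0, abs=0.1)
        assert fit.params["x"] == pytest.approx(0.8, abs=0.1)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=200)
        y = (x > 0).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separation
        assert fit.odds_ratios["ci_low"].isna().all()

    def test_constant_covariate_named(self):
        with pytest.raises(ValueError, match="constant.*flat"):
            fit_logistic([0, 1, 0, 1], pd.DataFrame({"flat": [1.0] * 4, "x": [1, 2, 3, 4.0]}))

    def test_collinear_covariate_named(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic([0, 1] * 5, pd.DataFrame({"x": x, "x2": 2 * x + 1}))

    def test_binary_covariate_reproduces_contingency_log_odds(self):
        # 2x2-encoded data: logistic slope == log odds ratio analytically
        a, b, c, d = 24, 4, 31, 59  # exposed-died, exposed-survived, ...
        exposure = np.array([1] * (a + b) + [0] * (c + d), float)
        outcome = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        fit = fit_logistic(outcome, pd.DataFrame({"exposure": exposure}))
        or_, _, _, _ = contingency_odds_ratio([[a, b], [c, d]])
        assert fit.params["exposure"] == pytest.approx(math.log(or_), abs=1e-6)

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        t = fit.odds_ratios
        assert ((t["ci_low"] <= t["odds_ratio"]) & (t["odds_ratio"] <= t["ci_high"])).all()
        assert (t["odds_ratio"] > 0).all()
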