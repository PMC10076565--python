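"""Univariate tests, logistic models, ROC/AUC, agreement, full workflow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from plaquemorph.calibration import HYPERLIPIDEMIA_TABLE
from plaquemorph.stats import (
    AnalysisConfig,
    StatsError,
    binormal_auc,
    combined_score,
    compare_categorical,
    compare_continuous,
    icc_agreement,
    multivariable_logistic,
    roc_auc,
    run_full_analysis,
    univariate_logistic,
)


def concordance_auc(scores, labels):
    """Exhaustive pairwise concordance (+1/2 for ties) — the AUC oracle."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestCompareContinuous:
    def test_identical_samples_show_no_difference(self):
        x = np.random.default_rng(0).normal(10, 2, size=40)
        res = compare_continuous(x, x.copy())
        assert res.p_value > 0.9

    def test_published_volume_parameters_are_separable(self):
        rng = np.random.default_rng(12)
        culprit = rng.normal(37.22, 11.46, size=111)
        nonculprit = rng.normal(17.77, 6.02, size=39)
        res = compare_continuous(culprit, nonculprit, feature="plaque_volume")
        assert res.p_value < 0.001

    def test_heavy_tails_route_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        skewed = rng.lognormal(0, 1.5, size=80)
        normal = rng.normal(5, 1, size=80)
        res = compare_continuous(skewed, normal)
        assert res.test_used == "mann_whitney"

    def test_normal_samples_route_to_welch_t(self):
        rng = np.random.default_rng(4)
        res = compare_continuous(
            rng.normal(0, 1, 60), rng.normal(0.5, 2, 60)
        )
        assert res.test_used == "t"

    def test_constant_column_warns_and_routes_nonparametric(self):
        x = np.full(10, 5.0)
        y = np.random.default_rng(1).normal(5, 1, size=10)
        with pytest.warns(UserWarning, match="constant"):
            res = compare_continuous(x, y)
        assert res.test_used == "mann_whitney"

    def test_too_small_group_rejected(self):
        with pytest.raises(StatsError):
            compare_continuous(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_type_one_error_is_calibrated(self):
        """Routed comparison holds its nominal 5% level under the null."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, size=30)
            b = rng.normal(0, 1, size=30)
            if compare_continuous(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestCompareCategorical:
    def test_hyperlipidemia_table_reproduces_published_p(self):
        res = compare_categorical(np.array(HYPERLIPIDEMIA_TABLE))
        assert res.test_used == "chi2_yates"
        assert res.statistic == pytest.approx(9.99, abs=0.01)
        assert round(res.p_value, 3) == 0.002

    def test_equal_proportions_fisher_p_is_one(self):
        res = compare_categorical(np.array([[2, 2], [2, 2]]))
        assert res.test_used == "fisher"
        assert res.p_value == pytest.approx(1.0)

    def test_sparse_table_routes_to_fisher(self):
        # coronary-disease-like counts: expected cell below 5
        res = compare_categorical(np.array([[2, 109], [0, 39]]))
        assert res.test_used == "fisher"

    def test_empty_margin_rejected(self):
        with pytest.raises(StatsError):
            compare_categorical(np.array([[0, 5], [0, 7]]))


class TestLogistic:
    def test_null_feature_gives_unit_odds_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        fit = univariate_logistic(x, y)
        term = fit.terms["x"]
        assert term.ci_low < 1.0 < term.ci_high
        assert term.odds_ratio == pytest.approx(1.0, abs=0.15)

    def test_recovers_known_coefficient_within_3_se(self):
        rng = np.random.default_rng(15)
        n, beta = 5000, 0.4
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.3 + beta * x)))
        y = (rng.random(n) < p).astype(int)
        fit = univariate_logistic(x, y)
        coef = fit.terms["x"].coefficient
        se = (np.log(fit.terms["x"].ci_high) - coef) / 1.96
        assert abs(coef - beta) < 3 * se

    def test_perfect_separation_is_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = np.concatenate([np.zeros(20), np.ones(20)]).astype(int)
        fit = univariate_logistic(x, y)
        assert fit.separation
        assert fit.terms["x"].ci_high == np.inf

    def test_two_null_features_both_cover_one(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.normal(size=(1500, 2)), columns=["a", "b"])
        y = rng.integers(0, 2, size=1500)
        fit = multivariable_logistic(X, y)
        for term in fit.terms.values():
            assert 0.8 < term.odds_ratio < 1.25
            assert term.ci_low < 1.1 and term.ci_high > 0.9

    def test_only_informative_features_significant_in_joint_model(self):
        rng = np.random.default_rng(33)
        n = 4000
        X = pd.DataFrame({
            "volume": rng.normal(size=n),
            "er_whole": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        lp = -0.2 + 0.9 * X["volume"] + 0.6 * X["er_whole"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = multivariable_logistic(X, y)
        assert fit.terms["volume"].p_value < 0.05
        assert fit.terms["er_whole"].p_value < 0.05
        assert fit.terms["noise1"].p_value > 0.05
        assert fit.terms["noise2"].p_value > 0.05

    def test_duplicated_column_warns_collinear(self):
        rng = np.random.default_rng(44)
        x = rng.normal(size=300)
        X = pd.DataFrame({"a": x, "b": x})
        y = (rng.random(300) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="collinear"):
            multivariable_logistic(X, y)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc(np.array([4.0, 3.0, 1.0, 0.5]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_random_labels_give_chance_auc(self):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=5000)
        labels = rng.integers(0, 2, size=5000)
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(0.5, abs=0.03)
        assert r.auc_ci_low < 0.5 < r.auc_ci_high

    def test_constant_score_degenerate(self):
        r = roc_auc(np.full(20, 3.0), np.r_[np.ones(10), np.zeros(10)])
        assert r.degenerate
        assert r.auc == 0.5

    @settings(derandomize=True, max_examples=40)
    @given(st.data())
    def test_auc_equals_pairwise_concordance(self, data):
        n = data.draw(st.integers(6, 50))
        scores = np.array([
            data.draw(st.integers(0, 8)) for _ in range(n)
        ], dtype=float)  # integer scores exercise ties
        labels = np.array(
            [data.draw(st.integers(0, 1)) for _ in range(n)]
        )
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels).auc == pytest.approx(
            concordance_auc(scores, labels)
        )

    def test_empirical_auc_converges_to_binormal_closed_form(self):
        rng = np.random.default_rng(64)
        n = 20000
        pos = rng.normal(42.44, 20.79, size=n)
        neg = rng.normal(16.66, 9.68, size=n)
        scores = np.concatenate([pos, neg])
        labels = np.r_[np.ones(n, int), np.zeros(n, int)]
        closed = binormal_auc(42.44, 20.79, 16.66, 9.68)
        assert abs(roc_auc(scores, labels).auc - closed) < 0.01

    def test_youden_point_maximizes_j(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([
            rng.normal(2, 1, 300), rng.normal(0, 1, 300)
        ])
        labels = np.r_[np.ones(300, int), np.zeros(300, int)]
        r = roc_auc(scores, labels)
        predicted = (scores >= r.youden_threshold).astype(int)
        sens = predicted[labels == 1].mean()
        spec = 1 - predicted[labels == 0].mean()
        assert sens == pytest.approx(r.sensitivity)
        assert spec == pytest.approx(r.specificity)
        assert sens + spec - 1 == pytest.approx((r.tpr - r.fpr).max())


class TestCombinedScore:
    def test_single_feature_model_reduces_to_feature_roc(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)])
        y = np.r_[np.ones(200, int), np.zeros(200, int)]
        fit = univariate_logistic(x, y, name="x")
        combined = combined_score(fit, pd.DataFrame({"x": x}))
        assert roc_auc(combined, y).auc == pytest.approx(
            roc_auc(x, y).auc
        )

    def test_combining_independent_signals_improves_auc(self):
        rng = np.random.default_rng(6)
        n = 3000
        X = pd.DataFrame({
            "a": rng.normal(size=n), "b": rng.normal(size=n)
        })
        lp = 0.8 * X["a"] + 0.8 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = multivariable_logistic(X, y)
        auc_combined = roc_auc(combined_score(fit, X), y).auc
        auc_single = max(roc_auc(X["a"].to_numpy(), y).auc,
                         roc_auc(X["b"].to_numpy(), y).auc)
        assert auc_combined >= auc_single

    def test_missing_column_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        fit = univariate_logistic(x, y, name="x")
        with pytest.raises(StatsError):
            combined_score(fit, pd.DataFrame({"other": x}))


class TestBinormalAuc:
    def test_equal_means_give_half(self):
        assert binormal_auc(5, 1, 5, 2) == 0.5

    def test_closed_form_matches_phi(self):
        v = binormal_auc(37.22, 11.46, 17.77, 6.02)
        assert v == pytest.approx(
            norm.cdf((37.22 - 17.77) / np.hypot(11.46, 6.02))
        )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(StatsError):
            binormal_auc(1, 0, 0, 1)


class TestAgreement:
    def test_identical_readers(self):
        x = np.arange(1.0, 9.0)
        res = icc_agreement(x, x.copy())
        assert res.icc == pytest.approx(1.0)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset_shows_as_bias_with_zero_loa_width(self):
        x = np.arange(1.0, 9.0)
        res = icc_agreement(x, x + 2.5)
        assert res.bias == pytest.approx(2.5)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_independent_readers_have_near_zero_icc(self):
        rng = np.random.default_rng(11)
        res = icc_agreement(rng.normal(size=500), rng.normal(size=500))
        assert abs(res.icc) < 0.15

    def test_both_constant_rejected(self):
        with pytest.raises(StatsError):
            icc_agreement(np.full(5, 1.0), np.full(5, 1.0))


class TestRunFullAnalysis:
    def test_default_cohort_produces_full_report(self, default_cohort):
        report = run_full_analysis(default_cohort)
        assert len(report.table1) >= 8
        assert len(report.table2) >= 10
        assert len(report.rocs) >= 3
        assert report.multivariable is not None
        assert report.combined_roc is not None
        # discrimination mirrors the underlying group separations
        assert report.rocs["plaque_volume"].auc > 0.85
        assert report.combined_roc.auc >= report.rocs["plaque_volume"].auc

    def test_shuffled_labels_remove_signal(self, default_cohort):
        shuffled = default_cohort.copy()
        rng = np.random.default_rng(100)
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        report = run_full_analysis(shuffled)
        for roc in report.rocs.values():
            assert abs(roc.auc - 0.5) < 0.17
        assert len(report.selected) <= 4  # chance-level selection only

    def test_rerun_is_deterministic(self, default_cohort):
        r1 = run_full_analysis(default_cohort)
        r2 = run_full_analysis(default_cohort)
        assert r1.table1.to_csv() == r2.table1.to_csv()
        assert r1.table2.to_csv() == r2.table2.to_csv()
        assert r1.table3().to_csv() == r2.table3().to_csv()

    def test_agreement_substudy_runs_on_subset(self, default_cohort):
        rng = np.random.default_rng(55)
        reader2 = default_cohort.copy()
        for col in ("plaque_volume", "wall_max"):
            reader2[col] = reader2[col] * (
                1 + rng.normal(0, 0.02, size=len(reader2))
            )
        config = AnalysisConfig(agreement_subset_n=30)
        report = run_full_analysis(default_cohort, config, reader2=reader2)
        assert report.agreement is not None
        vol = report.agreement.set_index("feature").loc["plaque_volume"]
        assert vol["icc"] > 0.9

    def test_missing_label_column_rejected(self, default_cohort):
        with pytest.raises(StatsError):
            run_full_analysis(
                default_cohort.drop(columns=["label"])
            )

    def test_single_class_rejected(self, default_cohort):
        culprit_only = default_cohort[default_cohort.label == "culprit"]
        with pytest.raises(StatsError):
            run_full_analysis(culprit_only)
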