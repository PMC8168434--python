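"""Group tests, redundancy filter, logistic reporting, ROC and DeLong."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from perfutex import (
    EQ4_MODEL_POST,
    InvalidInputError,
    delong_test,
    fit_logistic,
    mann_whitney,
    predict_prob,
    roc_analysis,
    run_full_analysis,
    spearman_filter,
    wald_or_ci,
)
from perfutex.phantom import CLASS_MOMENTS


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        # complete separation of {1,2} vs {3,4}: U = 0, exact p = 2/6
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_constant_pooled_sample_warns(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_exact_agrees_with_normal_approximation(self, rng):
        # at n1 = n2 = 16 without ties the two p-values differ by < 0.02
        for _ in range(20):
            x = rng.normal(0, 1, 16)
            y = rng.normal(0.5, 1, 16)
            exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            approx = mann_whitney(x, y)
            assert abs(exact.pvalue - approx.p_value) < 0.02

    def test_power_at_study_effect_size(self, rng):
        # post-treatment Ktrans moments of the two response groups
        mu_c, sd_c = CLASS_MOMENTS["post"]["CR"]["ktrans"]
        mu_p, sd_p = CLASS_MOMENTS["post"]["PR"]["ktrans"]
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.normal(mu_c, sd_c, 16)
            y = rng.normal(mu_p, sd_p, 16)
            if mann_whitney(x, y).p_value < 0.05:
                hits += 1
        assert hits / n_sim >= 0.70

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([], [1.0])


class TestSpearmanFilter:
    def test_perfectly_correlated_pair_keeps_smaller_p(self, rng):
        x = rng.random(30)
        tab = pd.DataFrame({"a": x, "b": 2 * x + 1})  # rho = 1
        kept = spearman_filter(tab, ["a", "b"], {"a": 0.01, "b": 0.02})
        assert kept == ["a"]

    def test_independent_features_all_retained(self, rng):
        tab = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        kept = spearman_filter(tab, list("abc"), {"a": 0.01, "b": 0.02, "c": 0.03})
        assert sorted(kept) == list("abc")

    def test_post_triple_survives_constructed_redundancy(self, rng):
        # three independent signals; each 'change' feature is rank-tied to
        # its 'post' partner, and the post features carry smaller p-values
        n = 40
        base = {f: rng.standard_normal(n) for f in ("ktrans", "ve", "entropy")}
        tab = pd.DataFrame(
            {
                **{f"{f}_post": v for f, v in base.items()},
                **{f"{f}_change": v + 0.05 * rng.standard_normal(n)
                   for f, v in base.items()},
            }
        )
        pvals = {
            "ktrans_post": 0.002, "ve_post": 0.002, "entropy_post": 0.047,
            "ktrans_change": 0.008, "ve_change": 0.005, "entropy_change": 0.048,
        }
        kept = spearman_filter(tab, list(pvals), pvals)
        assert sorted(kept) == ["entropy_post", "ktrans_post", "ve_post"]


class TestLogisticReporting:
    def test_zero_coefficient_gives_unit_odds_ratio(self):
        rep = wald_or_ci(0.0, 1.0)
        assert rep["odds_ratio"] == 1.0
        assert rep["ci_low"] < 1.0 < rep["ci_high"]

    def test_parameter_recovery_large_sample(self, rng):
        # simulate from a known model; MLE lands within 2 SE of truth
        n = 2000
        x = rng.standard_normal(n)
        true_beta = (-0.5, 1.2)
        p = 1 / (1 + np.exp(-(true_beta[0] + true_beta[1] * x)))
        y = np.where(rng.random(n) < p, "CR", "PR")
        tab = pd.DataFrame({"x": x})
        fit = fit_logistic(tab, ["x"], y)
        assert fit.converged and not fit.separation
        for name, truth in zip(("intercept", "x"), true_beta):
            t = fit.terms[name]
            assert abs(t.coef - truth) < 2 * t.std_error

    def test_separation_flagged_not_silent(self, rng):
        x = np.concatenate([rng.random(10), rng.random(10) + 5.0])
        y = np.array(["PR"] * 10 + ["CR"] * 10)
        with pytest.warns(UserWarning):
            fit = fit_logistic(pd.DataFrame({"x": x}), ["x"], y)
        assert fit.separation or not fit.converged

    def test_needs_both_classes(self):
        tab = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(InvalidInputError):
            fit_logistic(tab, ["x"], np.array(["CR", "CR"]))


class TestPredictProb:
    def test_intercept_only_evaluation(self):
        x = {"ktrans_post": 0.0, "ve_post": 0.0, "entropy_post": 0.0}
        p = predict_prob(EQ4_MODEL_POST, x)
        assert p == pytest.approx(1 / (1 + np.exp(-26.772)), rel=1e-12)

    def test_group_mean_evaluations_and_ordering(self):
        cr = {"ktrans_post": 0.117, "ve_post": 0.130, "entropy_post": 6.084}
        pr = {"ktrans_post": 0.299, "ve_post": 0.322, "entropy_post": 6.777}
        lp = (26.772 - 17.010 * 0.117 - 15.854 * 0.130 - 3.235 * 6.084)
        assert predict_prob(EQ4_MODEL_POST, cr) == pytest.approx(
            1 / (1 + np.exp(-lp)), rel=1e-12
        )
        assert predict_prob(EQ4_MODEL_POST, pr) < predict_prob(EQ4_MODEL_POST, cr)

    def test_monotone_decreasing_in_each_feature(self):
        base = {"ktrans_post": 0.2, "ve_post": 0.2, "entropy_post": 6.0}
        p0 = predict_prob(EQ4_MODEL_POST, base)
        for feat in ("ktrans_post", "ve_post", "entropy_post"):
            bumped = dict(base)
            bumped[feat] += 0.1
            assert predict_prob(EQ4_MODEL_POST, bumped) < p0

    def test_missing_feature_rejected(self):
        with pytest.raises(InvalidInputError):
            predict_prob(EQ4_MODEL_POST, {"ktrans_post": 0.1})


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 4], np.array(["PR", "PR", "CR", "CR"]),
                           positive_class="CR", direction=">")
        assert res.auc == 1.0
        assert 2 < res.cutoff < 3
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_auc_equals_rank_sum_identity(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.normal(size=30)
            labels = np.where(rng.random(30) < 0.5, "CR", "PR")
            if len(np.unique(labels)) < 2:
                continue
            res = roc_analysis(scores, labels, positive_class="CR", direction=">")
            sk = roc_auc_score((labels == "CR").astype(int), scores)
            assert res.auc == pytest.approx(sk, abs=1e-12)

    def test_tied_scores_get_half_credit(self):
        scores = [1.0, 1.0, 1.0, 1.0]
        labels = np.array(["CR", "CR", "PR", "PR"])
        res = roc_analysis(scores, labels, positive_class="CR", direction=">")
        assert res.auc == pytest.approx(0.5)

    def test_permutation_null_mean_half(self, rng):
        aucs = []
        scores = rng.normal(size=32)
        labels = np.array(["CR"] * 16 + ["PR"] * 16)
        for _ in range(2000):
            perm = rng.permutation(labels)
            aucs.append(
                roc_analysis(scores, perm, positive_class="CR", direction=">").auc
            )
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_analysis([1, 2], np.array(["CR", "CR"]))

    def test_auto_direction_flips_inverted_marker(self, rng):
        # lower marker values in the positive class
        scores = np.concatenate([rng.normal(0, 1, 16), rng.normal(2, 1, 16)])
        labels = np.array(["CR"] * 16 + ["PR"] * 16)
        res = roc_analysis(scores, labels, positive_class="CR")
        assert res.direction == "<" and res.auc >= 0.5


class TestDelong:
    def test_identical_scores_p_one(self, rng):
        scores = rng.normal(size=20)
        labels = np.array(["CR"] * 10 + ["PR"] * 10)
        assert delong_test(scores, scores, labels) == 1.0

    def test_null_calibration(self, rng):
        # two independent random score sets on 32 subjects: type-I error ~ 5%
        labels = np.array(["CR"] * 16 + ["PR"] * 16)
        rejections = 0
        n_sim = 600
        for _ in range(n_sim):
            a = rng.normal(size=32)
            b = rng.normal(size=32)
            if delong_test(a, b, labels) < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.025)

    def test_internal_auc_consistency(self, rng):
        scores_a = rng.normal(size=24)
        scores_b = rng.normal(size=24)
        labels = np.where(rng.random(24) < 0.5, "CR", "PR")
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = "CR", "PR"
        from perfutex.stats import _structural_components

        y = (labels == "CR").astype(int)
        v10, _ = _structural_components(scores_a, y)
        direct = roc_analysis(scores_a, labels, positive_class="CR", direction=">").auc
        assert v10.mean() == pytest.approx(direct, abs=1e-12)


class TestRunFullAnalysis:
    @staticmethod
    def _toy_table(rng, n=16, effect=1.5):
        rows = []
        for i in range(2 * n):
            grp = "CR" if i < n else "PR"
            shift = 0.0 if grp == "CR" else effect
            rows.append({
                "patient_id": f"P{i}",
                "group": grp,
                "ktrans_post": rng.normal(shift, 1),
                "ve_post": rng.normal(shift, 1),
                "entropy_post": rng.normal(shift, 1),
                "ktrans_change": rng.normal(shift, 1),
                "noise_pre": rng.normal(0, 1),
            })
        return pd.DataFrame(rows)

    def test_deterministic_on_fixed_table(self, rng):
        tab = self._toy_table(rng)
        a = run_full_analysis(tab)
        b = run_full_analysis(tab.copy())
        assert a["retained"] == b["retained"]
        assert a["combined_roc"].auc == b["combined_roc"].auc
        assert {k: v.p_value for k, v in a["group_tests"].items()} == {
            k: v.p_value for k, v in b["group_tests"].items()
        }

    def test_chain_selects_informative_features(self, rng):
        tab = self._toy_table(rng, effect=2.0)
        rep = run_full_analysis(tab)
        assert "noise_pre" not in rep["retained"]
        assert len(rep["retained"]) >= 1
        assert rep["combined_roc"].auc > 0.8
        assert "model_post" in rep["variants"]

    def test_null_table_rarely_selects(self, rng):
        # with pure-noise features, few replicates yield any candidate
        hits = 0
        for _ in range(30):
            tab = self._toy_table(rng, effect=0.0)
            rep = run_full_analysis(tab)
            hits += len(rep["candidates"]) > 0
        # 5 independent tests at alpha=0.05: P(any) ~ 0.23
        assert hits / 30 < 0.5
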