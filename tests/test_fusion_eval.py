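import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ischclock.fusion_eval import (auroc, auroc_delong,
                                   calibration_split_evaluate,
                                   compare_correlations_fisher,
                                   compare_r2_ftest, compare_slopes_z,
                                   error_vs_time_regression, family_columns,
                                   fit_fusion, mcnemar, r2_rmse,
                                   time_window_metrics, _fit_family)


class TestFusion:
    def test_perfect_cnn_estimate_fits_exactly(self):
        rng = np.random.default_rng(0)
        ots = np.exp(rng.uniform(0, np.log(48), 80))
        model = fit_fusion(np.log(ots), None, ots)
        pred = model.predict_log(np.log(ots), None)
        r2, _ = r2_rmse(pred, ots)
        assert r2 == pytest.approx(1.0, abs=1e-5)

    def test_empty_features_reduce_to_recalibration(self):
        rng = np.random.default_rng(1)
        ots = np.exp(rng.uniform(0, np.log(48), 60))
        cnn = np.log(ots) + rng.normal(0, 0.3, 60)
        model = fit_fusion(cnn, pd.DataFrame(index=range(60)), ots)
        assert model.feature_names == []
        assert np.all(np.isfinite(model.predict_log(cnn, None)))

    def test_informative_features_improve_held_out_r2(self):
        rng = np.random.default_rng(2)
        n = 400
        lt = rng.uniform(0, np.log(48), n)
        cnn = lt + rng.normal(0, 0.8, n)
        feats = pd.DataFrame({"good": lt + rng.normal(0, 0.3, n)})
        ots = np.exp(lt)
        half = n // 2
        with_f = fit_fusion(cnn[:half], feats.iloc[:half], ots[:half])
        without = fit_fusion(cnn[:half], None, ots[:half])
        r2_with, _ = r2_rmse(with_f.predict_log(cnn[half:],
                                                feats.iloc[half:]), ots[half:])
        r2_without, _ = r2_rmse(without.predict_log(cnn[half:], None),
                                ots[half:])
        assert r2_with > r2_without

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        ots = np.exp(rng.uniform(0, 1, 30))
        feats = pd.DataFrame({"a": rng.normal(size=30)})
        model = fit_fusion(np.log(ots), feats, ots)
        with pytest.raises(ValueError):
            model.predict_log(np.log(ots), pd.DataFrame({"b": ots}))


class TestR2Rmse:
    def test_perfect_prediction(self):
        true = np.array([1.0, 4.0, 12.0, 30.0])
        r2, rmse = r2_rmse(np.log(true), true)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_prediction_scores_zero(self):
        true = np.array([1.0, 4.0, 12.0, 30.0])
        r2, _ = r2_rmse(np.full(4, np.log(true).mean()), true)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_point_example(self):
        true = np.array([np.e, np.e ** 2, np.e ** 3, np.e ** 4])
        pred_log = np.array([1.5, 1.5, 3.5, 3.5])
        # SST = sum((log t - 2.5)^2) = 5; SSE = 4 * 0.25 = 1
        r2, rmse = r2_rmse(pred_log, true)
        assert r2 == pytest.approx(1 - 1 / 5, abs=1e-12)
        expected_rmse = np.sqrt(((np.exp(pred_log) - true) ** 2).mean()) * 60
        assert rmse == pytest.approx(expected_rmse, abs=1e-9)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            r2_rmse(np.zeros(5), np.full(5, 2.0))


class TestTimeWindows:
    def test_perfect_predictions_full_marks(self):
        hours = np.array([1.0, 5.0, 12.0, 30.0] * 3)
        out = time_window_metrics(hours, hours)
        assert out["f1"] == [1.0] * 4
        assert out["weighted_f1"] == 1.0
        assert out["weighted_accuracy"] == 1.0

    def test_single_window_predictions(self):
        true = np.array([1.0, 5.0, 12.0, 30.0])
        pred = np.full(4, 2.0)
        out = time_window_metrics(pred, true)
        assert out["f1"][0] == pytest.approx(2 * 1 / (1 + 4))
        assert out["accuracy"][3] == pytest.approx(0.75)

    def test_twelve_case_confusion_oracle(self):
        # hand-built: truth windows [0]*3+[1]*3+[2]*3+[3]*3; predictions
        # shift one case from each window into the next
        true = np.array([1, 1, 1, 5, 5, 5, 12, 12, 12, 30, 30, 30.0])
        pred = np.array([1, 1, 5, 5, 5, 12, 12, 12, 30, 30, 30, 30.0])
        out = time_window_metrics(pred, true)
        # window 0: tp=2, |t|=3, |p|=2 -> F1 = 4/5
        assert out["f1"][0] == pytest.approx(0.8)
        # window 1: tp=2, |t|=3, |p|=3 -> F1 = 4/6
        assert out["f1"][1] == pytest.approx(2 / 3)
        assert out["f1"][3] == pytest.approx(2 * 3 / (3 + 4))
        w = np.array([3, 3, 3, 3])
        expect = (np.array([0.8, 2 / 3, 2 / 3, 6 / 7]) * w).sum() / 12
        assert out["weighted_f1"] == pytest.approx(expect)

    def test_empty_truth_window_reported_missing(self):
        true = np.array([1.0, 2.0, 30.0, 40.0])
        pred = true.copy()
        out = time_window_metrics(pred, true)
        assert out["f1"][1] is None and out["f1"][2] is None
        assert out["weighted_f1"] == 1.0


class TestCalibrationSplits:
    def _table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        lt = rng.uniform(0, np.log(48), n)
        return pd.DataFrame({
            "ots": np.exp(lt),
            "ri": 0.04 * lt + rng.normal(0, 0.02, n),
            "cnn_log": lt + rng.normal(0, 0.5, n),
        })

    def test_single_split_reproducible(self):
        t = self._table()
        a = calibration_split_evaluate(t, "ri_gpr", n_splits=1, seed=5)
        b = calibration_split_evaluate(t, "ri_gpr", n_splits=1, seed=5)
        assert a.r2 == b.r2 and a.per_split_r2 == b.per_split_r2

    def test_calib_size_zero_uses_prior_model(self):
        t = self._table()
        cols, kind = family_columns("ri_linear", [])
        prior = _fit_family(t, cols, kind, 0)
        rep = calibration_split_evaluate(t, "ri_linear", calib_size=0,
                                         n_splits=2, seed=1,
                                         prior_model=prior)
        assert rep.r2 is not None
        assert rep.per_split_r2[0] == pytest.approx(rep.per_split_r2[1])

    def test_calib_size_must_be_smaller_than_set(self):
        t = self._table(20)
        with pytest.raises(ValueError):
            calibration_split_evaluate(t, "ri_gpr", calib_size=20)

    def test_larger_calibration_does_not_hurt(self):
        t = self._table(240, seed=7)
        small = calibration_split_evaluate(t, "ri_linear", calib_size=10,
                                           n_splits=10, seed=2)
        large = calibration_split_evaluate(t, "ri_linear", calib_size=120,
                                           n_splits=10, seed=2)
        assert large.r2 >= small.r2 - 0.05

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            family_columns("boosted_trees", [])


class TestDeLong:
    def test_identical_scores_give_zero_z(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        labels = rng.random(40) > 0.5
        a, b, z, p = auroc_delong(s, s, labels)
        assert a == b and z == 0.0 and p == 1.0

    def test_perfect_separation_auc_one(self):
        labels = np.array([False] * 10 + [True] * 10)
        scores = np.arange(20, dtype=float)
        assert auroc(scores, labels) == 1.0

    def test_variance_matches_bootstrap_within_20pct(self):
        rng = np.random.default_rng(1)
        n = 50
        labels = rng.random(n) > 0.4
        sa = labels + rng.normal(0, 0.9, n)
        sb = labels + rng.normal(0, 1.3, n)
        # DeLong variance of the AUC difference via its Z statistic
        auc_a, auc_b, z, _ = auroc_delong(sa, sb, labels)
        var_delong = ((auc_a - auc_b) / z) ** 2
        boot = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            if labels[idx].all() or not labels[idx].any():
                continue
            boot.append(auroc(sa[idx], labels[idx])
                        - auroc(sb[idx], labels[idx]))
        var_boot = np.var(boot)
        assert var_delong == pytest.approx(var_boot, rel=0.2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_delong([1.0, 2.0], [1.0, 2.0], [True, True])


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations_fisher(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == 1.0

    def test_closed_form_example(self):
        z, p = compare_correlations_fisher(0.6, 100, 0.3, 100)
        expect = (np.arctanh(0.6) - np.arctanh(0.3)) / np.sqrt(2 / 97)
        assert z == pytest.approx(expect, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expect)), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations_fisher(1.0, 50, 0.3, 50)
        with pytest.raises(ValueError):
            compare_correlations_fisher(0.5, 3, 0.3, 50)


class TestPartialF:
    def test_identical_fit_gives_zero(self):
        F, df, p = compare_r2_ftest(0.4, 0.4, 100, 1, 3)
        assert F == 0.0 and p == pytest.approx(1.0)

    def test_textbook_nested_comparison_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 40
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, 0.5, 0.0] + rng.normal(0, 1, n)
        small = sm.OLS(y, sm.add_constant(X[:, :1])).fit()
        large = sm.OLS(y, sm.add_constant(X)).fit()
        F, (df1, df2), p = compare_r2_ftest(small.rsquared, large.rsquared,
                                            n, 1, 3)
        F_sm, p_sm, df_sm = large.compare_f_test(small)
        assert F == pytest.approx(F_sm, rel=1e-9)
        assert p == pytest.approx(p_sm, rel=1e-9)
        assert df1 == int(df_sm)

    def test_invalid_nesting_rejected(self):
        with pytest.raises(ValueError):
            compare_r2_ftest(0.5, 0.6, 100, 3, 3)
        with pytest.raises(ValueError):
            compare_r2_ftest(0.6, 0.5, 100, 1, 3)


class TestMcNemar:
    def test_balanced_discordance_not_significant(self):
        a = np.array([True] * 10 + [False] * 10)
        b = np.array([False] * 10 + [True] * 10)
        chi2, p = mcnemar(a, b)
        assert p > 0.5

    def test_direct_formula_example(self):
        # b=20, c=5 discordant pairs -> (|15| - 1)^2 / 25 = 7.84
        a = np.array([True] * 20 + [False] * 5 + [True] * 10)
        b = np.array([False] * 20 + [True] * 5 + [True] * 10)
        chi2, p = mcnemar(a, b)
        assert chi2 == pytest.approx(7.84)

    def test_direction_agrees_with_exact_binomial(self):
        a = np.array([True] * 9 + [False] * 2 + [True] * 5)
        b = np.array([False] * 9 + [True] * 2 + [True] * 5)
        _, p_approx = mcnemar(a, b)
        p_exact = 2 * stats.binom.cdf(2, 11, 0.5)
        assert (p_approx < 0.05) == (p_exact < 0.05)

    def test_no_discordance_rejected(self):
        a = np.array([True, False, True])
        with pytest.raises(ValueError):
            mcnemar(a, a)


class TestErrorVsTime:
    def test_homoscedastic_errors_have_null_slope(self):
        rng = np.random.default_rng(3)
        ots = rng.uniform(1, 48, 300)
        err = np.abs(rng.normal(0, 60, 300))
        slope, (lo, hi), _ = error_vs_time_regression(err, ots)
        assert lo <= 0 <= hi

    def test_proportional_error_recovers_slope(self):
        ots = np.linspace(1, 48, 50)
        slope, _, _ = error_vs_time_regression(3.0 * ots, ots)
        assert slope == pytest.approx(3.0, abs=1e-9)

    def test_z_test_separates_distinct_slopes(self):
        rng = np.random.default_rng(4)
        ots = rng.uniform(1, 48, 500)
        e1 = 10.0 * ots + np.abs(rng.normal(0, 40, 500))
        e2 = 5.0 * ots + np.abs(rng.normal(0, 40, 500))
        s1, _, se1 = error_vs_time_regression(e1, ots)
        s2, _, se2 = error_vs_time_regression(e2, ots)
        z, p = compare_slopes_z(s1, se1, s2, se2)
        assert p < 0.05 and z > 0

    def test_zero_ots_variance_rejected(self):
        with pytest.raises(ValueError):
            error_vs_time_regression(np.ones(20), np.full(20, 5.0))
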