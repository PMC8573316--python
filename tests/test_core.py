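import numpy as np
import pandas as pd
import pytest

from envim.core import (
    ENMHyperparams,
    EnvimConfig,
    fit_all_metabolites,
    fit_baseline_enm,
    fit_enm_cv,
    fit_envim,
    make_fold_ids,
    predict_metabolites,
    rf_importance,
    threshold_subsets,
)
from envim.errors import DegenerateTargetError
from envim.tables import AbundanceTable, WeightMatrix
from envim.transforms import TransformParams, rank_inverse_normal

from conftest import make_table


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestFoldIds:
    def test_balanced_and_deterministic(self):
        a = make_fold_ids(47, 10, seed=3)
        b = make_fold_ids(47, 10, seed=3)
        np.testing.assert_array_equal(a, b)
        counts = np.bincount(a, minlength=10)
        assert counts.max() - counts.min() <= 1


class TestThresholdSubsets:
    def test_cumulative_selection_definition(self):
        sels = threshold_subsets(np.array([100.0, 55.0, 10.0, 0.0]))
        got = [(s.k, int(s.selected.sum())) for s in sels]
        assert got == [(90.0, 1), (50.0, 2), (10.0, 3), (0.0, 4)]

    def test_all_equal_importances_collapse(self):
        sels = threshold_subsets(np.full(4, 100.0))
        assert len(sels) == 1
        assert sels[0].k == 90.0 and sels[0].selected.all()

    def test_k_zero_selects_everything(self):
        sels = threshold_subsets(np.array([5.0, 80.0, 0.0]), K=(0,))
        assert len(sels) == 1 and sels[0].selected.all()

    def test_nestedness(self, rng):
        vi = rng.uniform(0, 100, 30)
        sels = threshold_subsets(vi)
        for hi, lo in zip(sels, sels[1:]):
            assert hi.k > lo.k
            assert set(np.flatnonzero(hi.selected)) <= set(np.flatnonzero(lo.selected))


class TestRFImportance:
    def test_planted_signal_tops_the_ranking(self):
        r = np.random.default_rng(0)
        X = r.normal(size=(200, 101))
        y = 3.0 * X[:, 0] + r.normal(0, 0.1, 200)
        vi = rf_importance(X, y, n_trees=100, mtry_grid=[33], seed=1)
        assert vi[0] == 100.0
        assert vi.min() == 0.0 and vi.max() == 100.0

    def test_pure_noise_still_rescaled(self):
        r = np.random.default_rng(1)
        vi = rf_importance(r.normal(size=(60, 10)), r.normal(size=60),
                           n_trees=50, mtry_grid=[3], seed=2)
        assert vi.max() == 100.0

    def test_deterministic(self):
        r = np.random.default_rng(2)
        X, y = r.normal(size=(60, 8)), r.normal(size=60)
        a = rf_importance(X, y, n_trees=50, mtry_grid=[2, 4], seed=7)
        b = rf_importance(X, y, n_trees=50, mtry_grid=[2, 4], seed=7)
        np.testing.assert_array_equal(a, b)

    def test_constant_target_rejected(self):
        with pytest.raises(DegenerateTargetError):
            rf_importance(np.random.default_rng(0).normal(size=(40, 3)), np.ones(40))


class TestElasticNetCV:
    def test_matches_ols_as_penalty_vanishes(self):
        r = np.random.default_rng(10)
        X = r.normal(size=(50, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = X @ beta + r.normal(0, 0.5, 50)
        hp = ENMHyperparams(alpha_grid=[0.5], lambdas=np.array([1e-8]), n_folds=5, seed=0)
        res = fit_enm_cv(X, y, hp)
        Xd = np.column_stack([np.ones(50), X])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(res.coefficients, ols[1:], atol=1e-4)
        np.testing.assert_allclose(res.intercept, ols[0], atol=1e-4)

    def test_matches_ridge_closed_form(self):
        r = np.random.default_rng(11)
        X = _standardize(r.normal(size=(80, 5)))
        y = r.normal(size=80)
        lam = 0.3
        hp = ENMHyperparams(alpha_grid=[0.0], lambdas=np.array([lam]), n_folds=5, seed=0)
        res = fit_enm_cv(X, y, hp)
        n = len(y)
        ridge = np.linalg.solve(X.T @ X + n * lam * np.eye(5), X.T @ y)
        np.testing.assert_allclose(res.coefficients, ridge, atol=1e-6)

    def test_null_model_at_lambda_max(self):
        r = np.random.default_rng(12)
        X = r.normal(size=(60, 4))
        y = r.normal(size=60)
        hp = ENMHyperparams(alpha_grid=[1.0], lambdas=np.array([1e6]), n_folds=5, seed=0)
        res = fit_enm_cv(X, y, hp)
        np.testing.assert_array_equal(res.coefficients, 0.0)
        assert res.intercept == pytest.approx(y.mean())


class TestEnvimFit:
    def _planted(self, seed=0, n=120, p=40):
        r = np.random.default_rng(seed)
        X = r.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:3] = [2.0, -1.5, 1.0]
        y = X @ beta + r.normal(0, 0.5, n)
        return X, y

    def test_k_zero_reduces_to_plain_enm(self):
        X, y = self._planted()
        hp = ENMHyperparams(n_folds=5, lambda_path_length=30, seed=4)
        fit = fit_envim(X, y, K=(0,), hp=hp)
        plain = fit_enm_cv(X, y, hp)
        np.testing.assert_allclose(fit.coefficients, plain.coefficients, atol=1e-12)
        assert fit.cv_mse == plain.cv_mse
        assert fit.best_k == 0.0

    def test_thresholding_never_hurts_cv_mse(self):
        X, y = self._planted(seed=5)
        hp = ENMHyperparams(n_folds=5, lambda_path_length=30, seed=4)
        rfp = dict(n_trees=80, mtry_grid=[13], n_folds=3)
        from envim.core import RFParams

        fit_full = fit_envim(X, y, K=(0,), hp=hp)
        fit_vi = fit_envim(X, y, hp=hp, rf=RFParams(**rfp))
        assert fit_vi.cv_mse <= fit_full.cv_mse + 1e-12

    def test_coefficients_zero_below_threshold(self):
        X, y = self._planted(seed=6)
        hp = ENMHyperparams(n_folds=5, lambda_path_length=30, seed=4)
        from envim.core import RFParams

        fit = fit_envim(X, y, hp=hp, rf=RFParams(n_trees=80, mtry_grid=[13], n_folds=3))
        below = fit.importance < fit.best_k
        np.testing.assert_array_equal(fit.coefficients[below], 0.0)


def _paired_tables(seed=0, n=60, p=20, n_met=3):
    r = np.random.default_rng(seed)
    X = r.uniform(0.5, 2.0, size=(n, p))
    genes = make_table(X, modality="DNA")
    Z = rank_inverse_normal(X)
    M = np.column_stack([
        np.exp(0.8 * Z[:, 0] - 0.5 * Z[:, 1] + r.normal(0, 0.3, n)),
        np.exp(r.normal(0, 1, n)),
        np.exp(0.7 * Z[:, 2] + r.normal(0, 0.3, n)),
    ])[:, :n_met]
    metab = make_table(M / 100.0, modality="METABOLITE", prefix=("s", "m"))
    return genes, metab


SMALL_CFG = dict(
    k_grid=(0.0, 50.0), alpha_grid_size=4, n_folds=5, n_trees=60,
    mtry_grid=[6], rf_tune_folds=3, lambda_path_length=20,
)


class TestFitAllMetabolites:
    def test_failures_isolated_and_report_complete(self):
        genes, metab = _paired_tables()
        metab.data["m1"] = 0.001  # constant metabolite cannot be fitted
        w, report, params = fit_all_metabolites(genes, metab, EnvimConfig(seed=1, **SMALL_CFG))
        assert len(report) == 3
        assert (report["status"] == "failed").sum() == 1
        assert report.loc["m1", "status"] == "failed"
        np.testing.assert_array_equal(w.coefficients[:, 1], 0.0)

    def test_serial_equals_parallel(self):
        genes, metab = _paired_tables(seed=3)
        cfg1 = EnvimConfig(seed=2, n_jobs=1, **SMALL_CFG)
        cfg2 = EnvimConfig(seed=2, n_jobs=2, **SMALL_CFG)
        w1, _, _ = fit_all_metabolites(genes, metab, cfg1)
        w2, _, _ = fit_all_metabolites(genes, metab, cfg2)
        np.testing.assert_array_equal(w1.coefficients, w2.coefficients)
        np.testing.assert_array_equal(w1.intercepts, w2.intercepts)


class TestPredict:
    def _weights(self):
        params = TransformParams(["m0"], omega=[0.0], delta=[0.0])
        w = WeightMatrix(["g0", "g1", "g2"], ["m0"], np.array([0.5]),
                         np.array([[1.0], [0.0], [-0.5]]))
        return w, params

    def test_no_shared_genes_gives_intercept_only(self):
        w, params = self._weights()
        t = make_table(np.random.default_rng(0).uniform(1, 2, (5, 2)),
                       prefix=("s", "other"))
        with pytest.warns(UserWarning):
            pred = predict_metabolites(w, t, params)
        np.testing.assert_allclose(pred.values, np.exp(0.5))

    def test_zero_weight_gene_is_irrelevant(self):
        w, params = self._weights()
        r = np.random.default_rng(1)
        X = r.uniform(1, 2, (8, 3))
        full = make_table(X, prefix=("s", "g"))
        reduced = AbundanceTable(full.data[["g0", "g2"]], "RAW", "DNA")
        a = predict_metabolites(w, full, params)
        b = predict_metabolites(w, reduced, params)
        np.testing.assert_allclose(a.values, b.values)

    def test_training_data_reproduces_fitted_values(self):
        genes, metab = _paired_tables(seed=8, n_met=1)
        w, report, params = fit_all_metabolites(genes, metab, EnvimConfig(seed=3, **SMALL_CFG))
        a = predict_metabolites(w, genes, params)
        b = predict_metabolites(w, genes, params)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.std() > 0  # a real model, not a constant


class TestBaseline:
    def test_pure_noise_not_flagged_predictable(self):
        genes, metab = _paired_tables(seed=9, n_met=2)  # m1 is pure noise
        w, report, params = fit_baseline_enm(genes, metab, EnvimConfig(seed=4, **SMALL_CFG))
        assert "predictable" in report.columns
        assert not report.loc["m1", "predictable"]

    def test_strong_signal_flagged_predictable(self):
        genes, metab = _paired_tables(seed=10, n_met=1)
        _, report, _ = fit_baseline_enm(genes, metab, EnvimConfig(seed=5, **SMALL_CFG))
        assert report.loc["m0", "predictable"]
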