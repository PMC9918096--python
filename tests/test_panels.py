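"""Panel procedures: solver correctness, nested CV, elastic-net pipeline, BCa."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirseed import (PanelConfig, nested_loocv_logistic, glmnet_panel_selection,
                     refit_logistic_cv_auc, bca_bootstrap_ci, elastic_net_panel,
                     roc_curve)
from mirseed.panels import (enet_logistic_path, _fit_single, _fast_auc,
                            _balance_weights, _stratified_folds)

LEAN_GRID = {"C": [0.01, 1.0, 100.0], "penalty": ["l2"],
             "selector": ["f_score"], "n_features": [1, 4, 7]}

AUC90_SHIFT = np.sqrt(2.0) * sps.norm.ppf(0.9)   # binormal shift for AUC 0.9


def _planted(seed, n=90, p=7, shift=AUC90_SHIFT, pos=21):
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.array([1] * pos + [0] * (n - pos)))
    X = rng.normal(size=(n, p))
    X[:, 0] += shift * y
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    return table, y


class TestEnetSolver:
    """The internal coordinate-descent solver against sklearn's saga."""

    @pytest.mark.parametrize("alpha, C", [(1.0, 0.1), (0.0, 1.0),
                                          (0.5, 0.5), (0.5, 10.0)])
    def test_matches_sklearn_on_standardized_design(self, alpha, C, rng):
        from sklearn.linear_model import LogisticRegression
        n, p = 80, 6
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)      # align penalty conventions
        beta = np.array([1.5, -1.0, 0, 0, 0.5, 0])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        _, coef = _fit_single(X, y, 1.0 / (C * n), alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = LogisticRegression(penalty="elasticnet", l1_ratio=alpha, C=C,
                                    solver="saga", max_iter=50000,
                                    tol=1e-12).fit(X, y)
        np.testing.assert_allclose(coef, sk.coef_[0], atol=5e-3)

    def test_lambda_max_zeroes_all_coefficients(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.integers(0, 2, 50).astype(float)
        _, coef = _fit_single(X, y, 10.0, 1.0)
        np.testing.assert_array_equal(coef, 0.0)

    def test_observation_weights_shift_the_fit(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(float)
        w_up = np.where(y == 1, 5.0, 1.0)
        b0_plain, _ = _fit_single(X, y, 1e-3, 0.0)
        b0_up, _ = _fit_single(X, y, 1e-3, 0.0, w_up)
        assert b0_up > b0_plain


class TestNestedLoocv:
    def test_planted_signal_recovered(self):
        table, y = _planted(0, shift=3.0)
        res = nested_loocv_logistic(table, y, grid=LEAN_GRID, seed=0)
        assert res.cv_auc > 0.9
        assert res.feature_importance.index[0] == "f0"
        assert res.feature_importance.iloc[0] > 0.5

    def test_importance_sums_to_one_and_descends(self):
        table, y = _planted(1)
        res = nested_loocv_logistic(table, y, grid=LEAN_GRID, seed=1)
        imp = res.feature_importance
        assert imp.sum() == pytest.approx(1.0)
        assert (imp >= 0).all()
        assert np.all(np.diff(imp.to_numpy()) <= 1e-12)

    def test_one_outoffold_prediction_per_sample(self):
        table, y = _planted(2, n=40)
        res = nested_loocv_logistic(table, y, grid=LEAN_GRID, seed=2)
        assert res.pooled_predictions.notna().all()
        assert len(res.pooled_predictions) == 40

    def test_duplicated_signal_column_keeps_auc(self):
        table, y = _planted(3, shift=3.0)
        res1 = nested_loocv_logistic(table, y, grid=LEAN_GRID, seed=3)
        dup = table.copy()
        dup["f0_copy"] = table["f0"]
        grid = dict(LEAN_GRID, n_features=[1, 4, 8])
        res2 = nested_loocv_logistic(dup, y, grid=grid, seed=3)
        assert abs(res1.cv_auc - res2.cv_auc) < 0.1
        covered = res2.feature_importance[["f0", "f0_copy"]].sum()
        assert covered > 0.5


class TestGlmnetPanel:
    def test_strong_predictor_kept_in_all_folds(self):
        table, y = _planted(0, shift=3.0)
        res = glmnet_panel_selection(table, y, PanelConfig(seed=0))
        assert "f0" in res.kept_features
        assert (res.fold_coefs["f0"] != 0).all()

    def test_pure_noise_mostly_empty_panels(self):
        empties = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            table = pd.DataFrame(rng.normal(size=(90, 7)),
                                 columns=[f"f{i}" for i in range(7)])
            y = rng.permutation(np.array([1] * 21 + [0] * 69))
            res = glmnet_panel_selection(table, y, PanelConfig(seed=seed))
            empties += res.empty_panel
        assert empties >= 2

    def test_feature_scaling_does_not_change_selection(self):
        table, y = _planted(4, shift=2.0)
        res1 = glmnet_panel_selection(table, y, PanelConfig(seed=7))
        scaled = table.copy()
        scaled["f0"] = scaled["f0"] * 1000.0
        res2 = glmnet_panel_selection(scaled, y, PanelConfig(seed=7))
        assert res1.kept_features == res2.kept_features

    def test_small_class_rejected(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(20, 4)))
        y = np.array([1] + [0] * 19)
        with pytest.raises(ValueError):
            glmnet_panel_selection(table, y, PanelConfig(seed=0))


class TestRefit:
    def test_label_feature_gives_perfect_cv_auc(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        table = pd.DataFrame({"leaky": y.astype(float),
                              "noise": rng.normal(size=40)})
        cv_auc, coef, pvals, pooled, sep = refit_logistic_cv_auc(table, y)
        assert cv_auc == 1.0
        assert sep   # the label feature perfectly separates

    def test_null_features_near_chance(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(rng.normal(size=(60, 3)))
            y = rng.permutation(np.array([1] * 20 + [0] * 40))
            aucs.append(refit_logistic_cv_auc(table, y)[0])
        assert 0.35 < np.mean(aucs) < 0.6

    def test_pooled_auc_consistent_with_roc_module(self):
        table, y = _planted(6, n=50)
        cv_auc, _, _, pooled, _ = refit_logistic_cv_auc(table, y)
        ok = pooled.notna().to_numpy()
        roc = roc_curve(pooled.to_numpy()[ok], y[ok])
        assert cv_auc == pytest.approx(roc.auc)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            refit_logistic_cv_auc(pd.DataFrame(index=range(10)),
                                  np.zeros(10, dtype=int))


class TestBcaBootstrap:
    def test_reduces_to_percentile_when_symmetric(self, rng):
        y = np.tile([0, 1], 40)
        scores = rng.normal(size=80) + 0.9 * y
        lo, hi = bca_bootstrap_ci(scores, y, n_boot=20000, seed=0)
        # reconstruct the plain percentile interval from the same machinery
        idx = np.random.default_rng(0).integers(0, 80, size=(20000, 80))
        boot = np.array([_fast_auc(y[i], scores[i]) for i in idx[:4000]])
        p_lo, p_hi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(p_lo, abs=0.03)
        assert hi == pytest.approx(p_hi, abs=0.03)

    def test_separated_data_upper_limit_is_one(self):
        y = np.array([0] * 10 + [1] * 10)
        scores = np.arange(20.0)
        lo, hi = bca_bootstrap_ci(scores, y, n_boot=2000, seed=1)
        assert hi == 1.0
        assert lo <= 1.0

    def test_matches_scipy_bca_oracle(self, rng):
        y = rng.integers(0, 2, 50)
        scores = rng.normal(size=50) + 0.8 * y
        lo, hi = bca_bootstrap_ci(scores, y, n_boot=10000, seed=3)
        res = sps.bootstrap(
            (scores, y),
            lambda s, yy: _fast_auc(np.asarray(yy), np.asarray(s)),
            paired=True, vectorized=False, n_resamples=10000,
            method="BCa", random_state=11)
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.02)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.02)

    def test_more_resamples_converge(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 40)
        scores = rng.normal(size=40) + 0.7 * y
        lo1, hi1 = bca_bootstrap_ci(scores, y, n_boot=5000, seed=1)
        lo2, hi2 = bca_bootstrap_ci(scores, y, n_boot=50000, seed=2)
        assert lo1 == pytest.approx(lo2, abs=0.03)
        assert hi1 == pytest.approx(hi2, abs=0.03)

    def test_degenerate_distribution_collapses(self):
        y = np.array([0, 0, 1, 1] * 5)
        scores = y.astype(float)          # AUC 1 in every resample with both classes
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_bootstrap_ci(scores, y, n_boot=2000, seed=0)
        assert lo == hi == 1.0


class TestEndToEndPanel:
    def test_planted_panel_full_pipeline(self):
        table, y = _planted(8, shift=3.0)
        res = elastic_net_panel(table, y, PanelConfig(seed=8, n_boot=2000))
        assert "f0" in res.kept_features
        assert res.cv_auc > 0.85
        assert res.ci_low <= res.cv_auc <= res.ci_high
        assert res.p_value < 0.001

    def test_ci_bounds_ordered(self):
        table, y = _planted(9, shift=1.0)
        res = elastic_net_panel(table, y, PanelConfig(seed=9, n_boot=2000))
        if not res.empty_panel:
            assert res.ci_low <= res.ci_high


class TestHelpers:
    def test_balance_weights_average_one_per_class_total(self):
        y = np.array([1] * 10 + [0] * 30)
        w = _balance_weights(y)
        assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())
        assert w.mean() == pytest.approx(1.0)

    def test_stratified_folds_cover_everything(self):
        y = np.array([1] * 9 + [0] * 21)
        folds = _stratified_folds(y, 5, np.random.default_rng(0))
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(30))
        for f in folds:
            assert (y[f] == 1).any()
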