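"""Wrapper selection, linear SVR, cross-validation and fold bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.base import clone

from thermohrv import regression as reg
from thermohrv.signals import DegenerateInputError


def make_linear_problem(rng, n=32, p=8, signal_col=3, noise=0.0):
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
    )
    y = 2.0 * X.iloc[:, signal_col].to_numpy() + noise * rng.normal(size=n)
    return X, y


class TestZscoreFeatures:
    def test_columns_standardized(self, rng):
        X = pd.DataFrame(rng.normal(5, 3, size=(40, 6)))
        Xz, record = reg.zscore_features(X)
        assert np.all(np.abs(Xz.mean(axis=0)) < 1e-12)
        assert np.allclose(Xz.std(axis=0, ddof=1), 1.0, atol=1e-12)
        assert record.transform(X).equals(Xz)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            Xz, record = reg.zscore_features(X)
        assert list(Xz.columns) == ["a"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            reg.zscore_features(pd.DataFrame({"a": [1.0]}))
        with pytest.raises(DegenerateInputError):
            reg.zscore_features(pd.DataFrame({"a": np.ones(10)}))


class TestWrapperSelect:
    def test_informative_column_is_found(self, rng):
        X, y = make_linear_problem(rng, noise=0.1)
        selected = reg.wrapper_select(X, y, reg.ModelConfig(rng_seed=0))
        assert "f3" in selected

    def test_pure_noise_selects_few_features(self, rng):
        X = pd.DataFrame(rng.normal(size=(32, 20)),
                         columns=[f"f{i}" for i in range(20)])
        y = rng.normal(size=32)
        selected = reg.wrapper_select(X, y, reg.ModelConfig(rng_seed=0))
        assert 1 <= len(selected) <= reg.ModelConfig().max_features
        assert len(selected) <= 2  # adaptive threshold rejects chance gains

    def test_cap_one_returns_single_best_feature(self, rng):
        X, y = make_linear_problem(rng, noise=0.0)
        selected = reg.wrapper_select(X, y, reg.ModelConfig(max_features=1))
        assert selected == ["f3"]

    def test_constant_target_rejected(self, rng):
        X, _ = make_linear_problem(rng)
        with pytest.raises(DegenerateInputError):
            reg.wrapper_select(X, np.ones(len(X)), reg.ModelConfig())


class TestFitLinearSVR:
    def test_noiseless_linear_recovery(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 2.0 * X["x"].to_numpy()
        model = reg.fit_linear_svr(X, y, reg.ModelConfig(epsilon=1e-4))
        rms = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rms < 1e-3 * np.std(y)

    def test_constant_target_gives_flat_model(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=30)})
        model = reg.fit_linear_svr(X, np.full(30, 7.5))
        assert np.allclose(model.weights, 0.0)
        assert np.allclose(model.predict(X), 7.5)

    def test_duplicated_column_preserves_predictions(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 2.0 * X["x"].to_numpy() + 0.05 * rng.normal(size=40)
        X2 = pd.DataFrame({"x": X["x"], "x2": X["x"] * 1.0})
        m1 = reg.fit_linear_svr(X, y)
        m2 = reg.fit_linear_svr(X2, y)
        assert np.allclose(m1.predict(X), m2.predict(X2), atol=1e-6)


class TestCrossval:
    def test_perfect_linear_target_gives_unit_spearman(self, rng):
        # weak regularization and a narrow tube so the SVR can interpolate
        X, y = make_linear_problem(rng, p=3, signal_col=0, noise=0.0)
        folds = reg.random_fold_assignment(len(X), 5, np.random.default_rng(0))
        preds = reg.crossval_predict(X, y, folds, reg.ModelConfig(C=100.0, epsilon=1e-4))
        assert spearmanr(preds, y).statistic == pytest.approx(1.0)

    def test_permuted_target_mean_r_near_zero(self, rng):
        X, y = make_linear_problem(rng, p=3, signal_col=0, noise=0.0)
        rs = []
        for i in range(200):
            yp = rng.permutation(y)
            folds = reg.random_fold_assignment(len(X), 5, np.random.default_rng(i))
            preds = reg.crossval_predict(X, yp, folds, reg.ModelConfig())
            rs.append(spearmanr(preds, yp).statistic)
        assert abs(np.mean(rs)) < 0.1

    def test_no_leakage_corrupting_heldout_targets(self, rng):
        X, y = make_linear_problem(rng, p=4, noise=0.5)
        folds = reg.random_fold_assignment(len(X), 5, np.random.default_rng(3))
        base = reg.crossval_predict(X, y, folds, reg.ModelConfig())
        for fold in range(5):
            y_corrupt = y.copy()
            y_corrupt[folds == fold] = rng.normal(size=(folds == fold).sum()) * 100
            preds = reg.crossval_predict(X, y_corrupt, folds, reg.ModelConfig())
            assert np.allclose(preds[folds == fold], base[folds == fold])

    def test_single_fold_rejected(self, rng):
        X, y = make_linear_problem(rng)
        with pytest.raises(ValueError):
            reg.crossval_predict(X, y, np.zeros(len(X), dtype=int), reg.ModelConfig())

    def test_fold_sizes_near_equal_for_32_by_5(self):
        folds = reg.random_fold_assignment(32, 5, np.random.default_rng(0))
        sizes = sorted(np.bincount(folds), reverse=True)
        assert sizes == [7, 7, 6, 6, 6]


class TestBootstrap:
    def test_noiseless_linear_target_r_one_everywhere(self, rng):
        X, y = make_linear_problem(rng, p=3, signal_col=0, noise=0.0)
        cfg = reg.ModelConfig(n_bootstrap=50, rng_seed=4, C=100.0, epsilon=1e-4)
        boot = reg.bootstrap_cv(X, y, cfg)
        assert np.allclose(boot.r_per_iteration, 1.0)
        assert boot.r_sd == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproducible(self, rng):
        X, y = make_linear_problem(rng, noise=0.5)
        cfg = reg.ModelConfig(n_bootstrap=25, rng_seed=9)
        a = reg.bootstrap_cv(X, y, cfg)
        b = reg.bootstrap_cv(X, y, cfg)
        assert np.array_equal(a.r_per_iteration, b.r_per_iteration)
        assert a.representative_iteration == b.representative_iteration

    def test_representative_iteration_is_closest_to_mean(self, rng):
        X, y = make_linear_problem(rng, noise=1.0)
        boot = reg.bootstrap_cv(X, y, reg.ModelConfig(n_bootstrap=40, rng_seed=2))
        gaps = np.abs(boot.r_per_iteration - boot.r_mean)
        assert gaps[boot.representative_iteration] == pytest.approx(gaps.min())


class TestWrapperLinearSVREstimator:
    def test_fit_predict_and_fitted_attributes(self, rng):
        X, y = make_linear_problem(rng, noise=0.1)
        est = reg.WrapperLinearSVR(random_state=0).fit(X, y)
        assert "f3" in est.selected_features_
        assert est.coef_.shape == (len(est.selected_features_),)
        r = spearmanr(est.predict(X), y).statistic
        assert r > 0.95

    def test_get_params_and_clone_roundtrip(self):
        est = reg.WrapperLinearSVR(C=2.0, epsilon=0.05, random_state=7)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_unfitted_predict_raises(self, rng):
        X, _ = make_linear_problem(rng)
        with pytest.raises(Exception):
            reg.WrapperLinearSVR().predict(X)


class TestWeightsReport:
    def test_single_feature_table_and_prediction_roundtrip(self, rng):
        X = pd.DataFrame({"N_psd_breath": rng.normal(size=40)})
        y = -1.5 * X["N_psd_breath"].to_numpy()
        model = reg.fit_linear_svr(X, y)
        table = reg.weights_report(model)
        assert len(table) == 1
        assert table.loc[0, "roi"] == "N" and table.loc[0, "feature"] == "psd_breath"
        assert table.loc[0, "sign"] == "-"
        # reconstruct predictions from the serialized weights
        xz = (X.to_numpy().ravel() - model.x_mean[0]) / model.x_sd[0]
        recon = (xz * table.loc[0, "weight"] + model.intercept) * model.y_sd + model.y_mean
        assert np.allclose(recon, model.predict(X), atol=1e-12)

    def test_driving_feature_ranks_first(self, rng):
        X = pd.DataFrame(
            {
                "N_psd_breath": rng.normal(size=40),
                "G_mean": rng.normal(size=40),
                "NT_sd": rng.normal(size=40),
            }
        )
        y = 3.0 * X["N_psd_breath"].to_numpy() + 0.05 * rng.normal(size=40)
        table = reg.weights_report(reg.fit_linear_svr(X, y))
        assert table.loc[0, "roi"] == "N"
        assert table.loc[0, "feature"] == "psd_breath"
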