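"""Connectome ridge pipeline: cleaning, features, LOOCV, scoring, ICCs."""

import numpy as np
import pytest
from scipy import stats

from fmriboot.prediction import (
    ALPHA_GRID,
    clean_timeseries,
    connectivity_features,
    evaluate_model,
    fit_ridge_pipeline,
    model_reliability,
    model_validity,
    predict,
)
from fmriboot.synthetic import simulate_connectome_cohort


class TestCleaning:
    def _confounds(self, rng, T, q=24):
        return rng.normal(size=(T, q)) * 0.1

    def test_linear_trend_removed(self, rng):
        # a pure trend carries no signal at all after detrending
        T = 200
        trend = np.linspace(0, 5, T)[:, None] * np.ones((1, 3))
        out = clean_timeseries(trend, self._confounds(rng, T))
        assert np.abs(out).max() < 1e-8

    def test_bandpass_response(self, rng):
        # in-band 0.05 Hz dominates out-of-band 0.3 Hz after cleaning
        T = 600
        t = np.arange(T, dtype=float)
        mixed = (np.sin(2 * np.pi * 0.05 * t)
                 + np.sin(2 * np.pi * 0.3 * t))
        ts = np.column_stack([mixed, rng.normal(size=T)])
        out = clean_timeseries(ts, self._confounds(rng, T))
        spec = np.abs(np.fft.rfft(out[100:-100, 0]))
        freqs = np.fft.rfftfreq(T - 200, d=1.0)
        p_in = spec[np.argmin(np.abs(freqs - 0.05))]
        p_out = spec[np.argmin(np.abs(freqs - 0.3))]
        assert p_out < 0.1 * p_in

    def test_confound_copy_removed_exactly(self, rng):
        T = 200
        conf = self._confounds(rng, T)
        ts = np.column_stack([conf[:, 0], rng.normal(size=T)])
        out = clean_timeseries(ts, conf)
        assert out[:, 0].var() < 1e-10 * max(ts[:, 0].var(), 1e-30)

    def test_band_outside_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            clean_timeseries(rng.normal(size=(100, 2)),
                             self._confounds(rng, 100), tr_s=2.0,
                             band_hz=(0.01, 0.4))


class TestConnectivityFeatures:
    def test_4950_features_for_100_regions(self, rng):
        ts = [rng.normal(size=(60, 100)) for _ in range(2)]
        feats = connectivity_features(ts)
        assert feats.n_features == 4950

    @pytest.mark.parametrize("p,expected", [(4, 6), (10, 45)])
    def test_feature_count_contract(self, rng, p, expected):
        feats = connectivity_features([rng.normal(size=(40, p))])
        assert feats.n_features == expected

    def test_independent_series_near_zero(self, rng):
        feats = connectivity_features([rng.normal(size=(5000, 6))])
        assert np.abs(feats.matrix).max() < 0.1

    def test_shrinkage_pulls_duplicated_pair_below_one(self, rng):
        base = rng.normal(size=(80, 1))
        ts = np.column_stack([base, base + rng.normal(0, 1e-6, (80, 1)),
                              rng.normal(size=(80, 2))])
        feats = connectivity_features([ts])
        sample_corr = np.corrcoef(ts.T)[1, 0]
        # Ledoit-Wolf shrinks toward the diagonal target
        assert np.tanh(feats.matrix[0, 0]) < sample_corr
        assert np.all(np.isfinite(feats.matrix))


def _loocv_mse_explicit(Xs, y, alpha):
    """Leave-one-out by literally refitting n ridge models."""
    n = len(y)
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = Xs[keep], y[keep]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc = Xtr - xm
        w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(Xs.shape[1]),
                            Xc.T @ (ytr - ym))
        pred = (Xs[i] - xm) @ w + ym
        errs[i] = y[i] - pred
    return np.mean(errs**2)


class TestRidgePipeline:
    def test_closed_form_loocv_matches_explicit_refits(self, rng):
        from fmriboot.prediction import _loocv_mse_grid

        for _ in range(3):
            Xs = rng.normal(size=(12, 5))
            y = rng.normal(size=12)
            mse = _loocv_mse_grid(Xs, y, ALPHA_GRID)
            for a_i, alpha in enumerate(ALPHA_GRID):
                assert mse[a_i] == pytest.approx(
                    _loocv_mse_explicit(Xs, y, alpha), rel=1e-8)

    def test_selected_alpha_minimizes_loocv(self, rng):
        X = rng.normal(size=(30, 8))
        y = X[:, 0] + rng.normal(size=30)
        model = fit_ridge_pipeline(X, y)
        assert model.loocv_mse.min() == model.loocv_mse[
            list(model.alpha_grid).index(model.alpha)]

    def test_variance_filter(self, rng):
        X = rng.normal(size=(40, 3))
        X[:, 1] *= 0.05  # variance 0.0025 < 0.01 -> screened out
        model = fit_ridge_pipeline(X, rng.normal(size=40))
        np.testing.assert_array_equal(model.kept_mask, [True, False, True])

    def test_infinite_shrinkage_limit(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        from fmriboot.prediction import _ridge_solve

        coef, intercept = _ridge_solve((X - np.median(X, axis=0)), y, 1e9)
        preds = (X - np.median(X, axis=0)) @ coef + intercept
        np.testing.assert_allclose(preds, y.mean(), atol=1e-2)

    def test_alpha_grid_spans_20_log_spaced_values(self):
        assert len(ALPHA_GRID) == 20
        assert ALPHA_GRID[0] == pytest.approx(0.1)
        assert ALPHA_GRID[-1] == pytest.approx(10000.0)

    def test_agrees_with_sklearn_ridgecv(self, rng):
        from sklearn.linear_model import RidgeCV

        X = rng.normal(size=(25, 6)) * 3 + 1
        y = X[:, 0] - 0.5 * X[:, 2] + rng.normal(size=25)
        model = fit_ridge_pipeline(X, y)
        Xs = (X[:, model.kept_mask] - model.medians) / model.iqrs
        ref = RidgeCV(alphas=ALPHA_GRID).fit(Xs, y)
        assert model.alpha == pytest.approx(ref.alpha_)
        np.testing.assert_allclose(model.coefficients, ref.coef_, rtol=1e-6)


class TestModelSerialization:
    def test_json_roundtrip_predicts_identically(self, rng, tmp_path):
        from fmriboot.prediction import RidgeModel

        X = rng.normal(size=(30, 5)) * 2
        y = X[:, 1] + rng.normal(size=30)
        model = fit_ridge_pipeline(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = RidgeModel.from_json(path)
        np.testing.assert_allclose(predict(loaded, X), predict(model, X),
                                   rtol=1e-12)
        assert loaded.alpha == model.alpha


class TestEvaluation:
    def test_perfect_predictions(self, rng):
        X = rng.normal(size=(30, 3)) * 2
        y = X @ np.array([1.0, -1.0, 0.5])
        model = fit_ridge_pipeline(X, y)
        score = evaluate_model(model, X, y, n_perms=1000, seed=0)
        assert score.rank_corr > 0.99
        assert score.p_perm == pytest.approx(1 / 1001, abs=1e-3)

    def test_negative_r2_clipped(self, rng):
        X = rng.normal(size=(20, 3)) * 2
        model = fit_ridge_pipeline(X, rng.normal(size=20))
        Xt = rng.normal(size=(15, 3)) * 2
        score = evaluate_model(model, Xt, rng.normal(size=15) + 10.0,
                               n_perms=200, seed=1)
        assert score.r2 < 0
        assert score.r2_reported == 0.0

    def test_null_permutation_p_uniform(self, rng):
        # under no association the permutation p-value is uniform on (0,1]
        from fmriboot.prediction import RidgeModel

        model = RidgeModel(kept_mask=np.ones(3, bool), medians=np.zeros(3),
                           iqrs=np.ones(3),
                           coefficients=np.array([1.0, -0.5, 0.2]),
                           intercept=0.0, alpha=1.0)
        ps = []
        for i in range(200):
            X = rng.normal(size=(25, 3))
            y = rng.normal(size=25)
            score = evaluate_model(model, X, y, n_perms=99, seed=i)
            ps.append(score.p_perm)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestModelComparison:
    def _models(self, rng, n_models=4, n=40, k=6):
        X = rng.normal(size=(n, k)) * 2
        y = X[:, 0] + rng.normal(size=n)
        return [fit_ridge_pipeline(X[rng.integers(0, n, n)],
                                   y[rng.integers(0, n, n)])
                for _ in range(n_models)], X

    def test_identical_model_correlation_one(self, rng):
        models, X = self._models(rng, 1)
        corr = model_validity([models[0]], models[0])
        assert corr[0] == pytest.approx(1.0)

    def test_negated_coefficients(self, rng):
        models, X = self._models(rng, 1)
        import copy

        neg = copy.deepcopy(models[0])
        neg.coefficients = -neg.coefficients
        corr = model_validity([neg], models[0])
        assert corr[0] == pytest.approx(-1.0)

    def test_identical_models_icc_one(self, rng):
        models, X = self._models(rng, 1)
        pred_icc, coef_icc = model_reliability([models[0]] * 3, X)
        assert pred_icc.estimate == pytest.approx(1.0)
        assert coef_icc.estimate == pytest.approx(1.0)

    def test_noise_trained_models_icc_near_zero(self, rng):
        X = rng.normal(size=(60, 10)) * 2
        Xt = rng.normal(size=(40, 10)) * 2
        models = [fit_ridge_pipeline(X, rng.normal(size=60))
                  for _ in range(10)]
        pred_icc, _ = model_reliability(models, Xt)
        assert abs(pred_icc.estimate) < 0.1


class TestEndToEndRecovery:
    def test_causal_edge_signs_and_holdout_correlation(self):
        # parameter recovery at a scale where estimation noise is small
        cohort = simulate_connectome_cohort(
            n_subjects=900, p_regions=12, T=150, n_causal=6,
            target_r2=0.25, seed=42)
        cleaned = [clean_timeseries(cohort.timeseries[s], cohort.confounds[s])
                   for s in range(cohort.n_subjects)]
        feats = connectivity_features(cleaned)
        train = np.arange(700)
        test = np.arange(700, 900)
        model = fit_ridge_pipeline(feats.matrix[train], cohort.trait[train])
        score = evaluate_model(model, feats.matrix[test], cohort.trait[test],
                               n_perms=200, seed=0)
        assert score.rank_corr == pytest.approx(0.5, abs=0.15)
        full = model.full_coefficients()
        causal = np.flatnonzero(cohort.true_weights)
        assert np.all(np.sign(full[causal])
                      == np.sign(cohort.true_weights[causal]))
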