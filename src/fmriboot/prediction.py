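"""Connectome-based trait prediction with ridge regression.

Level 4 of the survey.  Per-subject time series are cleaned (linear
detrend, 0.01-0.1 Hz band-pass, columnwise standardization, nuisance
regression on 24 confounds), turned into Ledoit-Wolf-shrunk correlation
matrices, Fisher-z transformed, and flattened to the strict lower
triangle (p(p-1)/2 features; 4950 for 100 regions).  Models are ridge
regressions with the penalty chosen from 20 log-spaced values in
[0.1, 10000] by exact closed-form leave-one-out cross-validation; they
are scored on a fixed holdout test set by Spearman correlation and R²
(negative R² reported as 0), with permutation significance.

The closed-form LOOCV uses the hat-matrix identity
``e_loo_i = (y_i - yhat_i) / (1 - h_ii)``, which is exact for ridge with
an unpenalized intercept.  It is implemented in the kernel (n x n) form,
with one eigendecomposition of the centred Gram matrix shared across the
whole penalty grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.covariance import LedoitWolf

from .metrics import icc_c1

__all__ = [
    "ConnectivityFeatures",
    "RidgeModel",
    "ModelScore",
    "ALPHA_GRID",
    "clean_timeseries",
    "connectivity_features",
    "fit_ridge_pipeline",
    "predict",
    "evaluate_model",
    "model_validity",
    "model_reliability",
]

ALPHA_GRID = np.logspace(-1, 4, 20)  # 0.1 .. 10000 inclusive
VARIANCE_THRESHOLD = 0.01
ATANH_CLIP = 1.0 - 1e-7
BAND_HZ = (0.01, 0.1)


@dataclass
class ConnectivityFeatures:
    """Fisher-z lower-triangle connectivity per subject."""

    matrix: np.ndarray  # (n_subjects, p(p-1)/2)
    edge_index: np.ndarray  # (n_edges, 2) with i > j

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RidgeModel:
    """Fitted ridge pipeline: screening, scaling and coefficients."""

    kept_mask: np.ndarray  # over the full feature index
    medians: np.ndarray  # per kept feature
    iqrs: np.ndarray
    coefficients: np.ndarray  # per kept feature
    intercept: float
    alpha: float
    alpha_grid: np.ndarray = field(default_factory=lambda: ALPHA_GRID.copy())
    loocv_mse: np.ndarray | None = None
    n_iqr_dropped: int = 0

    def full_coefficients(self) -> np.ndarray:
        """Coefficients on the full feature index (dropped features -> 0)."""
        out = np.zeros(len(self.kept_mask))
        out[self.kept_mask] = self.coefficients
        return out

    def to_json(self, path) -> None:
        """Persist the fitted pipeline (screening, scaling, coefficients)."""
        import json

        payload = {
            "kept_mask": self.kept_mask.astype(int).tolist(),
            "medians": self.medians.tolist(),
            "iqrs": self.iqrs.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "alpha_grid": np.asarray(self.alpha_grid).tolist(),
            "n_iqr_dropped": self.n_iqr_dropped,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RidgeModel":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(kept_mask=np.asarray(d["kept_mask"], dtype=bool),
                   medians=np.asarray(d["medians"]),
                   iqrs=np.asarray(d["iqrs"]),
                   coefficients=np.asarray(d["coefficients"]),
                   intercept=d["intercept"], alpha=d["alpha"],
                   alpha_grid=np.asarray(d["alpha_grid"]),
                   n_iqr_dropped=d["n_iqr_dropped"])


@dataclass
class ModelScore:
    """Holdout performance of one fitted model."""

    rank_corr: float
    r2: float
    r2_reported: float
    p_perm: float
    n_perms: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# time-series cleaning and features


def clean_timeseries(
    ts: np.ndarray,
    confounds: np.ndarray,
    tr_s: float = 1.0,
    band_hz=BAND_HZ,
) -> np.ndarray:
    """Detrend, band-pass, standardize, and regress out confounds.

    Steps run in that order.  Confounds are detrended and filtered
    identically before the regression so that filtering cannot
    reintroduce removed nuisance signal; the regression includes an
    intercept.
    """
    ts = np.asarray(ts, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    T, q = confounds.shape
    if ts.shape[0] != T:
        raise ValueError("time series and confounds disagree on T")
    if T <= 2 * q:
        raise ValueError("need T > 2 * number of confounds")
    nyquist = 0.5 / tr_s
    lo, hi = band_hz
    if not (0.0 < lo < hi < nyquist):
        raise ValueError("band must lie strictly inside (0, Nyquist)")

    ts_raw_sd = ts.std(axis=0)
    ts = signal.detrend(ts, axis=0, type="linear")
    confounds = signal.detrend(confounds, axis=0, type="linear")
    sos = signal.butter(5, [lo, hi], btype="bandpass", fs=1.0 / tr_s, output="sos")
    ts = signal.sosfiltfilt(sos, ts, axis=0)
    confounds = signal.sosfiltfilt(sos, confounds, axis=0)

    # columns whose variance is numerically zero after detrend+filter
    # (relative to their raw scale) are left unscaled instead of being
    # blown up to unit variance
    sd = ts.std(axis=0)
    raw_sd = np.asarray(ts_raw_sd)
    degenerate = sd <= 1e-8 * np.maximum(raw_sd, 1e-300)
    ts = (ts - ts.mean(axis=0)) / np.where(degenerate, 1.0, sd)

    design = np.column_stack([np.ones(T), confounds])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def connectivity_features(cleaned_ts: list) -> ConnectivityFeatures:
    """Ledoit-Wolf correlations, Fisher z, strict lower triangle.

    Each subject's cleaned (T, p) series yields a shrunk covariance,
    converted to correlation, clipped just inside (-1, 1), atanh
    transformed, and flattened over the (i > j) lower triangle in fixed
    row-major order.
    """
    first = np.asarray(cleaned_ts[0])
    T, p = first.shape
    if T <= 3:
        raise ValueError("need more than 3 time points")
    rows, cols = np.tril_indices(p, -1)
    feats = np.empty((len(cleaned_ts), len(rows)))
    for s, ts in enumerate(cleaned_ts):
        cov = LedoitWolf(assume_centered=False).fit(np.asarray(ts)).covariance_
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        corr = np.clip(corr, -ATANH_CLIP, ATANH_CLIP)
        feats[s] = np.arctanh(corr[rows, cols])
    return ConnectivityFeatures(matrix=feats,
                                edge_index=np.column_stack([rows, cols]))


# ---------------------------------------------------------------------------
# ridge with closed-form LOOCV


def _loocv_mse_grid(Xs: np.ndarray, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Exact leave-one-out MSE for every penalty on the grid.

    Works in the kernel form: with centred features Xc and centred
    responses yc, the ridge smoother is Hc = G (G + aI)^-1 for the Gram
    matrix G = Xc Xc', and the full smoother including the unpenalized
    intercept has diagonal 1/n + diag(Hc).  The LOO residual is then
    (y_i - yhat_i) / (1 - h_ii), exactly.
    """
    n = Xs.shape[0]
    x_mean = Xs.mean(axis=0)
    Xc = Xs - x_mean
    y_mean = y.mean()
    yc = y - y_mean
    G = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(G)
    evals = np.maximum(evals, 0.0)
    Vy = evecs.T @ yc
    V2 = evecs**2
    mse = np.empty(len(alphas))
    for a_i, alpha in enumerate(alphas):
        shrink = evals / (evals + alpha)
        yhat = y_mean + evecs @ (shrink * Vy)
        h = 1.0 / n + V2 @ shrink
        loo = (y - yhat) / (1.0 - h)
        mse[a_i] = np.mean(loo**2)
    return mse


def _ridge_solve(Xs: np.ndarray, y: np.ndarray, alpha: float):
    """Ridge coefficients with an unpenalized intercept (kernel form)."""
    n = Xs.shape[0]
    x_mean = Xs.mean(axis=0)
    Xc = Xs - x_mean
    y_mean = y.mean()
    G = Xc @ Xc.T
    dual = np.linalg.solve(G + alpha * np.eye(n), y - y_mean)
    coef = Xc.T @ dual
    intercept = y_mean - x_mean @ coef
    return coef, intercept


def fit_ridge_pipeline(
    features: np.ndarray,
    trait: np.ndarray,
    alphas: np.ndarray = ALPHA_GRID,
) -> RidgeModel:
    """Variance screen, robust scaling, and LOOCV-tuned ridge fit.

    Features with training variance below 0.01 are removed; survivors
    are robustly scaled (median removed, interquartile range divided;
    zero-IQR features dropped with a count).  The penalty is the grid
    value minimizing the exact closed-form leave-one-out MSE, and the
    model is refit on all training rows at that penalty.
    """
    X = np.asarray(features.matrix if hasattr(features, "matrix") else features,
                   dtype=float)
    y = np.asarray(trait, dtype=float)
    n, n_full = X.shape
    if n < 3:
        raise ValueError("need at least 3 training subjects")
    alphas = np.asarray(alphas, dtype=float)

    kept = X.var(axis=0) >= VARIANCE_THRESHOLD
    medians = np.median(X[:, kept], axis=0)
    q75, q25 = np.percentile(X[:, kept], [75, 25], axis=0)
    iqrs = q75 - q25
    nonzero_iqr = iqrs > 0
    n_iqr_dropped = int((~nonzero_iqr).sum())
    if n_iqr_dropped:
        idx = np.flatnonzero(kept)
        kept[idx[~nonzero_iqr]] = False
        medians = medians[nonzero_iqr]
        iqrs = iqrs[nonzero_iqr]
    if not kept.any():
        raise ValueError("no features survived screening")

    Xs = (X[:, kept] - medians) / iqrs
    mse = _loocv_mse_grid(Xs, y, alphas)
    best = int(np.argmin(mse))
    coef, intercept = _ridge_solve(Xs, y, alphas[best])
    return RidgeModel(kept_mask=kept, medians=medians, iqrs=iqrs,
                      coefficients=coef, intercept=float(intercept),
                      alpha=float(alphas[best]), alpha_grid=alphas.copy(),
                      loocv_mse=mse, n_iqr_dropped=n_iqr_dropped)


def predict(model: RidgeModel, features) -> np.ndarray:
    X = np.asarray(features.matrix if hasattr(features, "matrix") else features,
                   dtype=float)
    Xs = (X[:, model.kept_mask] - model.medians) / model.iqrs
    return Xs @ model.coefficients + model.intercept


def evaluate_model(
    model: RidgeModel,
    features,
    trait: np.ndarray,
    n_perms: int = 1000,
    seed: int | None = None,
) -> ModelScore:
    """Score a model on the fixed holdout set.

    Spearman correlation and R² of predictions against the true trait;
    R² below zero is reported as zero.  Significance comes from a
    permutation test shuffling the test-set trait, with the add-one
    estimator p = (1 + #{|r_perm| >= |r_obs|}) / (n_perms + 1) so p is
    never zero.
    """
    y = np.asarray(trait, dtype=float)
    preds = predict(model, features)
    if np.ptp(preds) == 0:
        warnings.warn("constant predictions: rank correlation undefined",
                      RuntimeWarning)
        return ModelScore(np.nan, np.nan, 0.0, np.nan, n_perms, degenerate=True)
    rank_corr = float(stats.spearmanr(preds, y).statistic)
    sse = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    rng = np.random.default_rng(seed)
    pred_ranks = stats.rankdata(preds)
    y_ranks = stats.rankdata(y)
    count = 0
    for _ in range(n_perms):
        r = np.corrcoef(pred_ranks, rng.permutation(y_ranks))[0, 1]
        if abs(r) >= abs(rank_corr) - 1e-12:
            count += 1
    p_perm = (1 + count) / (n_perms + 1)
    return ModelScore(rank_corr=rank_corr, r2=r2, r2_reported=max(r2, 0.0),
                      p_perm=p_perm, n_perms=n_perms)


def model_validity(study_models: list, gold_model: RidgeModel) -> np.ndarray:
    """Pearson correlation of each study's coefficients with the gold's.

    Coefficients are compared on the common full feature index with
    dropped features contributing zeros.
    """
    gold = gold_model.full_coefficients()
    out = np.empty(len(study_models))
    for i, m in enumerate(study_models):
        c = m.full_coefficients()
        if np.ptp(c) == 0 or np.ptp(gold) == 0:
            warnings.warn("zero-variance coefficient vector", RuntimeWarning)
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(c, gold)[0, 1]
    return out


def model_reliability(study_models: list, test_features):
    """Agreement among study models: predictions and coefficients.

    Returns ``(prediction_icc, coefficient_icc)`` -- ICC(C,1) with test
    subjects as units and studies as raters, and ICC(C,1) with features
    as units and studies as raters.
    """
    if len(study_models) < 2:
        raise ValueError("need at least 2 study models")
    preds = np.column_stack([predict(m, test_features) for m in study_models])
    coefs = np.column_stack([m.full_coefficients() for m in study_models])
    return icc_c1(preds), icc_c1(coefs)
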