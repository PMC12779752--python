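"""Shared statistical kernels.

One-sample t maps, Holm step-down correction, intraclass correlation
coefficients (two-way consistency and one-way binary), the Hedges
small-sample bias factor, and noncentral-t power for the one-sample test.
These are the primitives every analysis level builds on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ICCResult",
    "one_sample_t",
    "holm_adjust",
    "icc_c1",
    "icc_binary_oneway",
    "hedges_factor",
    "power_one_sample_t",
    "min_n_one_sample_t",
]


@dataclass
class ICCResult:
    """An intraclass correlation estimate with its confidence interval.

    ``model`` is ``"twoway_consistency"`` for ICC(C,1) -- the single-measure
    two-way random-effects consistency coefficient -- or ``"oneway_binary"``
    for the one-way random-effects estimate on a 0/1 matrix.  ``degenerate``
    flags matrices with no usable between-unit variability.
    """

    estimate: float
    ci_low: float
    ci_high: float
    model: str
    n_units: int
    n_raters: int
    degenerate: bool = False


def one_sample_t(values: np.ndarray):
    """One-sample t-test against zero for each column of ``values``.

    Parameters
    ----------
    values : (n_subjects, n_units) or (n_subjects,) array

    Returns
    -------
    t, df, p : arrays (scalars collapse for 1-D input); p is two-sided.

    Columns with zero variance are degenerate: they get p=0 when the mean is
    nonzero (the test statistic diverges) and p=1 when the mean is zero,
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    n = values.shape[0]
    if n < 2:
        raise ValueError("one_sample_t requires at least 2 observations")
    df = n - 1
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if np.any(zero_var):
        warnings.warn("zero-variance columns in one_sample_t", RuntimeWarning)
        t = np.where(zero_var, np.sign(mean) * np.inf, t)
        t = np.where(zero_var & (mean == 0), 0.0, t)
        p = np.where(zero_var, np.where(mean == 0, 1.0, 0.0), p)
    if squeeze:
        return float(t[0]), df, float(p[0])
    return t, df, p


def holm_adjust(p_values: np.ndarray, alpha: float = 0.05):
    """Holm step-down familywise error correction.

    Returns ``(adjusted_p, reject)``; adjusted p-values are monotone in the
    sorted order and capped at 1.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy(), np.zeros(0, dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="holm")
    return p_adj, reject


def _twoway_mean_squares(ratings: np.ndarray):
    """Row (unit) and residual mean squares of the additive two-way layout."""
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((ratings - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, mse


def icc_c1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1): single-measure two-way random-effects consistency.

    ``ratings`` is a complete units x raters matrix.  The estimate is
    (MSR - MSE) / (MSR + (k-1) MSE) from the additive two-way ANOVA; the
    confidence interval follows the F-distribution construction of
    McGraw & Wong for the consistency coefficient.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("icc_c1 needs a 2-D matrix with >=2 units and >=2 raters")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("icc_c1 requires a complete (finite) matrix")
    n, k = ratings.shape
    msr, mse = _twoway_mean_squares(ratings)
    denom = msr + (k - 1) * mse
    if denom <= 0:
        return ICCResult(np.nan, np.nan, np.nan, "twoway_consistency", n, k, True)
    est = (msr - mse) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        lo = hi = est
    else:
        f_obs = msr / mse
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    return ICCResult(float(est), float(lo), float(hi), "twoway_consistency", n, k)


def _oneway_icc_point(binary: np.ndarray) -> float:
    """One-way random-effects ANOVA moment estimator of the ICC."""
    n, k = binary.shape
    grand = binary.mean()
    row_means = binary.mean(axis=1)
    ss_between = k * np.sum((row_means - grand) ** 2)
    ss_within = np.sum((binary - row_means[:, None]) ** 2)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return np.nan
    return (msb - msw) / denom


def icc_binary_oneway(
    binary: np.ndarray, n_boot: int = 100, seed: int | None = None
) -> ICCResult:
    """One-way random-effects ICC for a binary units x raters matrix.

    The point estimate is the ANOVA moment estimator applied to the 0/1
    entries; the confidence interval is a percentile bootstrap over units
    (``n_boot`` resamples).  A matrix whose entries are all identical carries
    no between-unit information and is flagged degenerate.
    """
    binary = np.asarray(binary, dtype=float)
    if binary.ndim != 2 or binary.shape[0] < 2 or binary.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 units and >=2 raters")
    if not np.all(np.isin(binary, (0.0, 1.0))):
        raise ValueError("entries must be 0 or 1")
    n, k = binary.shape
    if binary.min() == binary.max():
        return ICCResult(np.nan, np.nan, np.nan, "oneway_binary", n, k, True)
    est = _oneway_icc_point(binary)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = _oneway_icc_point(binary[idx])
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        lo = hi = np.nan
    else:
        lo, hi = np.percentile(boot, [2.5, 97.5])
    return ICCResult(float(est), float(lo), float(hi), "oneway_binary", n, k,
                     degenerate=not np.isfinite(est))


def hedges_factor(n: int) -> float:
    """Exact small-sample bias-correction factor J for a one-sample design.

    J = Gamma(df/2) / (sqrt(df/2) * Gamma((df-1)/2)) with df = n - 1;
    multiplying Cohen's d by J yields Hedges' g.  J increases with n and
    tends to 1; it lies in (0, 1) for n >= 3.  At n = 2 the bias of d is
    unbounded (one degree of freedom) and J collapses to its limit 0.
    """
    if n < 2:
        raise ValueError("hedges_factor requires n >= 2")
    df = n - 1
    return float(np.exp(
        special.gammaln(df / 2) - 0.5 * np.log(df / 2) - special.gammaln((df - 1) / 2)
    ))


def power_one_sample_t(
    d: float, n: int, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Power of the one-sample t-test from the noncentral t distribution.

    Noncentrality is ``d * sqrt(n)`` with ``n - 1`` degrees of freedom.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        tcrit = stats.t.isf(alpha / 2, df)
        power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    else:
        tcrit = stats.t.isf(alpha, df)
        power = stats.nct.sf(tcrit, df, nc)
    return float(power)


def min_n_one_sample_t(
    d: float,
    power_target: float = 0.80,
    alpha: float = 0.05,
    two_sided: bool = True,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n at which the one-sample t-test reaches the target power."""
    if not (alpha < power_target < 1):
        raise ValueError("power target must lie in (alpha, 1)")
    if d == 0:
        raise ValueError("power cannot exceed alpha when d = 0")
    n = 2
    while n <= n_max:
        if power_one_sample_t(d, n, alpha, two_sided) >= power_target:
            return n
        n += 1
    raise ValueError("no n <= n_max reaches the target power")
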