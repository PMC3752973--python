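"""Simple (Preacher-Hayes) mediation with a bootstrap test of the indirect effect.

Three OLS regressions partition the effect of an independent variable X
(here: diagnostic group) on an outcome Y (the seed -> DLPFC signed path
coefficient) into a direct part and a part flowing through a mediator M
(the first eigenvariate of the seed's aberrant functional connectivity):

    m = i_1 + a x           (+ covariates)
    y = i_2 + c' x + b m    (+ covariates)
    y = i_3 + c x           (+ covariates)

The indirect effect is ``a * b``; for linear models with identical
covariate sets the decomposition ``c = c' + a b`` is exact.  Its confidence
interval comes from case-resampling bootstrap (resample subjects, refit all
paths), with the bias-corrected percentile interval as the default and the
plain percentile interval as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MediationResult", "fit_mediation"]


@dataclass
class MediationResult:
    """Effect decomposition with bootstrap confidence interval.

    ``prop_mediated`` is ``ab / c``; it is NaN (and ``prop_mediated_stable``
    False) when the total effect is numerically zero, and should be treated
    with caution whenever \\|c\\| is small.
    """

    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ci_low: float
    ci_high: float
    prop_mediated: float
    prop_mediated_stable: bool
    n_boot: int
    ci_type: str
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    n: int


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and their two-sided p values for y ~ X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(np.diag(cov))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, p


def _paths(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, Z: np.ndarray
) -> tuple[float, float, float, float]:
    """(a, b, c, c_prime) from the three regressions."""
    n = x.size
    base = np.column_stack([np.ones(n), x, Z])
    a = np.linalg.lstsq(base, m, rcond=None)[0][1]
    full = np.column_stack([np.ones(n), x, m, Z])
    coef = np.linalg.lstsq(full, y, rcond=None)[0]
    c_prime, b = coef[1], coef[2]
    c = np.linalg.lstsq(base, y, rcond=None)[0][1]
    return float(a), float(b), float(c), float(c_prime)


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    rng: np.random.Generator | None = None,
    ci_type: str = "bias-corrected",
    alpha: float = 0.05,
) -> MediationResult:
    """Fit the simple mediation model and bootstrap the indirect effect.

    Parameters
    ----------
    x, m, y :
        Independent variable (typically binary diagnosis), mediator scores
        and outcome, one value per subject (n >= 10, no missing values).
    covariates :
        Optional columns included in every regression.
    n_boot :
        Bootstrap iterations for the CI of ``a * b`` (default 5,000).
    ci_type :
        "bias-corrected" (default) or "percentile".
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if m.size != n or y.size != n:
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError("mediation requires at least 10 subjects")
    if not (np.isfinite(x).all() and np.isfinite(m).all() and np.isfinite(y).all()):
        raise ValueError("missing values are not allowed")
    if x.std() == 0 or m.std() == 0:
        raise ValueError("x and m must have nonzero variance")
    if ci_type not in {"bias-corrected", "percentile"}:
        raise ValueError("ci_type must be 'bias-corrected' or 'percentile'")
    Z = (
        np.empty((n, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1)
    )
    rng = rng or np.random.default_rng()

    a, b, c, c_prime = _paths(x, m, y, Z)
    ab = a * b

    base = np.column_stack([np.ones(n), x, Z])
    full = np.column_stack([np.ones(n), x, m, Z])
    _, p_base_m = _ols(m, base)
    _, p_full = _ols(y, full)
    _, p_base_y = _ols(y, base)

    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, mb, yb = x[idx], m[idx], y[idx]
        if xb.std() == 0 or mb.std() == 0:
            boots[i] = np.nan
            continue
        ab_, bb_, _, _ = _paths(xb, mb, yb, Z[idx])
        boots[i] = ab_ * bb_
    boots = boots[np.isfinite(boots)]

    if ci_type == "percentile":
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        # bias-corrected percentile: shift quantile levels by the bias z0
        prop_below = np.mean(boots < ab)
        prop_below = min(max(prop_below, 1.0 / boots.size), 1 - 1.0 / boots.size)
        z0 = stats.norm.ppf(prop_below)
        za = stats.norm.ppf(alpha / 2)
        lo_level = stats.norm.cdf(2 * z0 + za)
        hi_level = stats.norm.cdf(2 * z0 - za)
        lo, hi = np.quantile(boots, [lo_level, hi_level])

    stable = abs(c) > 1e-12
    prop = ab / c if stable else float("nan")
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, ab=ab,
        ci_low=float(lo), ci_high=float(hi),
        prop_mediated=float(prop), prop_mediated_stable=bool(stable),
        n_boot=n_boot, ci_type=ci_type,
        p_a=float(p_base_m[1]), p_b=float(p_full[2]),
        p_c=float(p_base_y[1]), p_c_prime=float(p_full[1]),
        n=n,
    )
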