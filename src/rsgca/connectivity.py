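"""Bivariate lag-1 signed-path-coefficient Granger causality and seed FC.

The directed estimator: both series are z-scored, then the present of the
target is regressed on an intercept, its own lag-1 past and the lag-1 past of
the source,

    y_t = b0 + b_yy * y_{t-1} + b_xy * x_{t-1} + e_t,   t = 2..T.

``b_xy`` is the signed path coefficient of x on y: positive values are read
as excitatory influence, negative as inhibitory.  Both directions are fitted
(the model is deliberately bivariate, so opposite-signed influences can
coexist), and the net causal flow of a pair is ``b_xy - b_yx``.

Instantaneous (zero-lag) functional connectivity is the Pearson correlation
of seed and target with its Fisher z transform — a deliberately separate
quantity: lagged directed coefficients and zero-lag coupling measure
different things, and the suite checks that purely instantaneous coupling
produces large FC with null directed coefficients.

Degenerate targets (zero variance, collinearity with the seed) are flagged
explicitly rather than silently reported as zero influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateSeriesError",
    "PathCoefficientMap",
    "NetFlowMap",
    "FCMap",
    "pairwise_gca",
    "seed_gca_map",
    "net_flow",
    "fc_map",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series has (numerically) zero variance."""


_MIN_LEN = 10


@dataclass
class PathCoefficientMap:
    """Per-target signed lag-1 path coefficients from one seed.

    ``beta_xy[i]`` is seed -> target i, ``beta_yx[i]`` target i -> seed.
    ``flags[i]`` is an empty string for valid targets, otherwise the reason
    the coefficient is undefined (the beta is NaN in that case).
    """

    subject_id: str
    seed: str
    targets: list[str]
    beta_xy: np.ndarray
    beta_yx: np.ndarray
    lag_order: int = 1
    lag_seconds: float = 2.5
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.flags:
            self.flags = [""] * len(self.targets)


@dataclass
class NetFlowMap:
    """Per-target net causal flow ``beta_xy - beta_yx``."""

    subject_id: str
    seed: str
    targets: list[str]
    net: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass
class FCMap:
    """Per-target zero-lag Pearson r and Fisher z for one seed."""

    subject_id: str
    seed: str
    targets: list[str]
    r: np.ndarray
    z: np.ndarray
    flags: list[str] = field(default_factory=list)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd


def _lag1_beta(x: np.ndarray, y: np.ndarray) -> float:
    """OLS coefficient of x_{t-1} in y_t ~ [1, y_{t-1}, x_{t-1}].

    Returns NaN if the design is numerically rank deficient (e.g. y == x).
    """
    X = np.column_stack([np.ones(x.size - 1), y[:-1], x[:-1]])
    resp = y[1:]
    gram = X.T @ X
    # Rank check on the correlation scale so it is insensitive to units.
    scale = np.sqrt(np.diag(gram))
    cond = np.linalg.cond(gram / np.outer(scale, scale))
    if not np.isfinite(cond) or cond > 1e10:
        return float("nan")
    beta = np.linalg.solve(gram, X.T @ resp)
    return float(beta[2])


def pairwise_gca(
    x: np.ndarray, y: np.ndarray, zscore: bool = True
) -> tuple[float, float]:
    """Signed lag-1 path coefficients ``(beta_xy, beta_yx)`` for one pair.

    Parameters
    ----------
    x, y :
        Equal-length series (>= 10 points), nonzero variance.
    zscore :
        Standardize both series before the regressions (the default, making
        coefficients scale free and comparable across targets and subjects).
        The raw option exists for exact-arithmetic checks.

    Returns
    -------
    (beta_xy, beta_yx) :
        x-to-y and y-to-x coefficients.  A collinear pair (e.g. ``y`` is an
        exact copy of ``x``) yields NaN for the affected direction rather
        than a silent zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < _MIN_LEN:
        raise ValueError(f"series too short: {x.size} < {_MIN_LEN}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateSeriesError("zero-variance series")
    if zscore:
        x, y = _zscore(x), _zscore(y)
    return _lag1_beta(x, y), _lag1_beta(y, x)


def seed_gca_map(
    seed: np.ndarray,
    targets: np.ndarray,
    target_names: list[str] | None = None,
    subject_id: str = "",
    seed_name: str = "seed",
    lag_seconds: float = 2.5,
) -> PathCoefficientMap:
    """Apply :func:`pairwise_gca` seed-versus-every-column of ``targets``."""
    seed = np.asarray(seed, dtype=float).ravel()
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n_t = targets.shape[1]
    names = target_names if target_names is not None else [
        f"target_{i}" for i in range(n_t)
    ]
    bxy = np.full(n_t, np.nan)
    byx = np.full(n_t, np.nan)
    flags = [""] * n_t
    for i in range(n_t):
        col = targets[:, i]
        try:
            bxy[i], byx[i] = pairwise_gca(seed, col)
        except DegenerateSeriesError:
            flags[i] = "zero-variance"
            continue
        if np.isnan(bxy[i]) or np.isnan(byx[i]):
            flags[i] = "collinear"
    return PathCoefficientMap(
        subject_id=subject_id, seed=seed_name, targets=list(names),
        beta_xy=bxy, beta_yx=byx, lag_seconds=lag_seconds, flags=flags,
    )


def net_flow(pmap: PathCoefficientMap) -> NetFlowMap:
    """Net causal flow per target: ``beta_xy - beta_yx``; flags propagate."""
    return NetFlowMap(
        subject_id=pmap.subject_id,
        seed=pmap.seed,
        targets=list(pmap.targets),
        net=pmap.beta_xy - pmap.beta_yx,
        flags=list(pmap.flags),
    )


def fc_map(
    seed: np.ndarray,
    targets: np.ndarray,
    target_names: list[str] | None = None,
    subject_id: str = "",
    seed_name: str = "seed",
) -> FCMap:
    """Pearson r of the seed with every target column, with Fisher z.

    ``z = atanh(r)``; |r| numerically at 1 (the target *is* the seed) is
    flagged and its z left as +-inf.
    """
    seed = np.asarray(seed, dtype=float).ravel()
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n_t = targets.shape[1]
    names = target_names if target_names is not None else [
        f"target_{i}" for i in range(n_t)
    ]
    if seed.std(ddof=1) == 0:
        raise DegenerateSeriesError("zero-variance seed")
    r = np.full(n_t, np.nan)
    flags = [""] * n_t
    s = _zscore(seed)
    for i in range(n_t):
        col = targets[:, i]
        if col.std(ddof=1) == 0:
            flags[i] = "zero-variance"
            continue
        r[i] = float(np.clip((s * _zscore(col)).sum() / (s.size - 1), -1.0, 1.0))
        if abs(r[i]) >= 1.0 - 1e-12:
            flags[i] = "self-correlation"
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0))
    return FCMap(subject_id=subject_id, seed=seed_name, targets=list(names),
                 r=r, z=z, flags=flags)
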