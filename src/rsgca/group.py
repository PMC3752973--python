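"""Random-effects group statistics over per-subject connectivity maps.

One-sample and covariate-adjusted two-sample t maps, familywise-error
control by permutation maxT (sign flipping for one-sample tests, group-label
permutation with Freedman-Lane residualization under covariates), search
volume masks derived from one-sample results, cluster extent filtering on a
voxel grid, Bonferroni-adjusted follow-up tests, and first-eigenvariate
summaries of multi-target clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "GroupDesign",
    "GroupStatMap",
    "Cluster",
    "ClusterSet",
    "one_sample_map",
    "two_sample_map",
    "fwe_correct",
    "mask_from_one_sample",
    "cluster_filter",
    "followup_tests",
    "eigenvariate",
]


@dataclass
class GroupDesign:
    """Subject-level design for between-group tests.

    ``group`` is coded 0/1 (1 = patient by convention); ``gender`` 0/1.
    Age and gender enter as covariates of no interest; ``extra`` columns are
    appended as further covariates.
    """

    subject_ids: list[str]
    group: np.ndarray
    age: np.ndarray | None = None
    gender: np.ndarray | None = None
    extra: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float).ravel()
        n = self.group.size
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids and group must have equal length")
        if len(np.unique(self.group)) != 2:
            raise ValueError("both groups must be non-empty")
        for name in ("age", "gender", "extra"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_1d(np.asarray(v, dtype=float))
                if v.ndim == 1:
                    v = v[:, None]
                if v.shape[0] != n or not np.isfinite(v).all():
                    raise ValueError(f"covariate {name} has wrong length or NaNs")
                setattr(self, name, v)

    def covariates(self) -> np.ndarray:
        """Covariates-of-no-interest matrix (n x k), possibly empty."""
        cols = [v for v in (self.age, self.gender, self.extra) if v is not None]
        return np.hstack(cols) if cols else np.empty((self.group.size, 0))


@dataclass
class GroupStatMap:
    """Per-target t statistics with uncorrected and (optional) FWE p values."""

    targets: list[str]
    t: np.ndarray
    df: int
    p_unc: np.ndarray
    p_fwe: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.flags:
            self.flags = [""] * len(self.targets)

    @property
    def direction(self) -> np.ndarray:
        return np.sign(self.t)


def one_sample_map(values: np.ndarray, targets: list[str] | None = None) -> GroupStatMap:
    """Per-target one-sample t test of subject values against zero.

    ``values`` is subjects x targets; df = n - 1; two-sided p.  Targets with
    zero variance across subjects are flagged (t = NaN).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if n < 3:
        raise ValueError("one-sample map requires at least 3 subjects")
    names = targets if targets is not None else [f"target_{i}" for i in range(p)]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    flags = ["" if s > 0 else "zero-variance" for s in sd]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    df = n - 1
    p_unc = 2.0 * stats.t.sf(np.abs(t), df)
    return GroupStatMap(targets=list(names), t=t, df=df, p_unc=p_unc, flags=flags)


def _design_matrix(design: GroupDesign) -> np.ndarray:
    X = np.column_stack(
        [np.ones(design.group.size), design.group, design.covariates()]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("group design matrix is collinear")
    return X


def _contrast_t(values: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic of the group column (column 1) for every target column."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ values
    resid = values - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    gg = np.linalg.inv(X.T @ X)[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / np.sqrt(sigma2 * gg)
    return t, df


def two_sample_map(
    values: np.ndarray, design: GroupDesign, targets: list[str] | None = None
) -> GroupStatMap:
    """Covariate-adjusted between-group t map.

    Per target, fits ``value ~ intercept + group + covariates`` and reports
    the t statistic of the group contrast.  With no covariates this equals
    the pooled-variance two-sample t exactly.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = targets if targets is not None else [
        f"target_{i}" for i in range(values.shape[1])
    ]
    X = _design_matrix(design)
    t, df = _contrast_t(values, X)
    p_unc = 2.0 * stats.t.sf(np.abs(t), df)
    flags = ["" if np.isfinite(ti) else "degenerate" for ti in t]
    return GroupStatMap(targets=list(names), t=t, df=df, p_unc=p_unc, flags=flags)


def fwe_correct(
    values: np.ndarray,
    kind: str = "one_sample",
    design: GroupDesign | None = None,
    n_perm: int = 5000,
    mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """maxT permutation FWE-corrected p values within a mask.

    One-sample maps are permuted by sign flipping subject rows; two-sample
    maps by permuting group labels, with Freedman-Lane residualization when
    covariates are present (the permuted statistic is computed on permuted
    reduced-model residuals plus the reduced-model fit).  The corrected p of
    a target is the rank of its observed \\|t\\| in the null distribution of
    the maximum \\|t\\| over the mask, with the add-one correction
    ``(1 + #{maxT >= |t|}) / (n_perm + 1)``.

    Returns an array of corrected p values (NaN outside the mask).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if mask is None:
        mask = np.ones(p, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rng = rng or np.random.default_rng()
    v = values[:, mask]

    if kind == "one_sample":
        mean = v.mean(axis=0)
        sd = v.std(axis=0, ddof=1)
        t_obs = mean / (sd / np.sqrt(n))
        max_t = np.empty(n_perm)
        for b in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)[:, None]
            vb = v * signs
            sb = vb.std(axis=0, ddof=1)
            tb = vb.mean(axis=0) / (sb / np.sqrt(n))
            max_t[b] = np.nanmax(np.abs(tb))
    elif kind == "two_sample":
        if design is None:
            raise ValueError("two-sample correction requires a design")
        X = _design_matrix(design)
        t_obs, _ = _contrast_t(v, X)
        Z = np.column_stack([np.ones(n), design.covariates()])
        # Freedman-Lane: permute reduced-model residuals
        gamma = np.linalg.pinv(Z) @ v
        fit = Z @ gamma
        resid = v - fit
        pinv = np.linalg.pinv(X)
        gg = np.linalg.inv(X.T @ X)[1, 1]
        df = n - X.shape[1]
        max_t = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            vb = fit + resid[perm]
            beta = pinv @ vb
            sigma2 = ((vb - X @ beta) ** 2).sum(axis=0) / df
            with np.errstate(divide="ignore", invalid="ignore"):
                tb = beta[1] / np.sqrt(sigma2 * gg)
            max_t[b] = np.nanmax(np.abs(tb))
    else:
        raise ValueError(f"unknown kind {kind!r}")

    p_fwe_masked = (1.0 + (max_t[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (
        n_perm + 1.0
    )
    out = np.full(p, np.nan)
    out[mask] = p_fwe_masked
    return out


def mask_from_one_sample(stat_map: GroupStatMap, alpha: float = 0.05) -> np.ndarray:
    """Search-volume mask: targets significant in either direction.

    Uses FWE-corrected p values when present, otherwise uncorrected ones.
    """
    p = stat_map.p_fwe if stat_map.p_fwe is not None else stat_map.p_unc
    with np.errstate(invalid="ignore"):
        return np.asarray(p <= alpha) & np.isfinite(stat_map.t)


@dataclass
class Cluster:
    """A connected set of supra-threshold targets on the spatial grid."""

    member_indices: list[int]
    size: int
    peak_index: int
    peak_stat: float
    peak_coord: tuple[int, ...]
    sign: int


@dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_filter(
    t_values: np.ndarray,
    coords: np.ndarray,
    primary_threshold: float,
    k: int = 30,
) -> ClusterSet:
    """Connected supra-threshold components with extent >= ``k``.

    ``coords`` holds integer grid coordinates (targets x ndim).  Positive
    and negative exceedances are clustered separately using face
    connectivity (6-neighbour in 3D, 4-neighbour in 2D).
    """
    t_values = np.asarray(t_values, dtype=float).ravel()
    coords = np.atleast_2d(np.asarray(coords, dtype=int))
    if coords.shape[0] != t_values.size:
        raise ValueError("coords must have one row per target")
    ndim = coords.shape[1]
    origin = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - origin + 1)
    flat_index = {}
    grid_t = np.zeros(shape)
    for i, c in enumerate(coords):
        pos = tuple(c - origin)
        flat_index[pos] = i
        grid_t[pos] = t_values[i]

    structure = ndimage.generate_binary_structure(ndim, 1)  # face connectivity
    clusters: list[Cluster] = []
    for sign in (1, -1):
        supra = sign * grid_t >= primary_threshold
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            where = np.argwhere(labels == lab)
            members = [flat_index[tuple(pos)] for pos in where]
            if len(members) < k:
                continue
            stats_ = t_values[members]
            peak_local = int(np.argmax(sign * stats_))
            clusters.append(
                Cluster(
                    member_indices=sorted(members),
                    size=len(members),
                    peak_index=members[peak_local],
                    peak_stat=float(stats_[peak_local]),
                    peak_coord=tuple(int(x) for x in coords[members[peak_local]]),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: -abs(c.peak_stat))
    return ClusterSet(clusters)


def followup_tests(
    values_by_group: dict[str, np.ndarray],
    n_comparisons: int = 8,
) -> dict[str, dict[str, float]]:
    """Per-group one-sample follow-up tests with Bonferroni adjustment.

    For each group's vector of subject values (e.g. mean coefficient within
    a significant cluster), reports t, df, the raw two-sided p and the
    Bonferroni-adjusted ``min(1, n_comparisons * p)``.
    """
    out: dict[str, dict[str, float]] = {}
    for group, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float).ravel()
        n = vals.size
        t, p = stats.ttest_1samp(vals, 0.0)
        out[group] = {
            "t": float(t),
            "df": n - 1,
            "p_raw": float(p),
            "p_bonferroni": float(min(1.0, n_comparisons * p)),
            "mean": float(vals.mean()),
        }
    return out


def eigenvariate(values: np.ndarray) -> np.ndarray:
    """First-eigenvariate summary of a subjects x targets value matrix.

    The first left singular vector of the column-mean-centred matrix,
    scaled to unit variance and sign-oriented to correlate positively with
    the per-subject row mean.  With a single target this reduces to the
    standardized column.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("eigenvariate requires at least 2 subjects")
    centered = values - values.mean(axis=0)
    if not centered.any():
        raise ValueError("eigenvariate of an all-constant matrix is undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, 0] * s[0]
    scores = scores / scores.std(ddof=1)
    row_mean = centered.mean(axis=1)
    if row_mean.std() > 0 and np.corrcoef(scores, row_mean)[0, 1] < 0:
        scores = -scores
    return scores
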