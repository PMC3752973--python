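"""PCA composites and the severity regression.

Three first-principal-component composites summarize the patient data —
illness severity over the six clinical variables, salience-execution loop
integrity over the three net causal flows among rAI, rDLPFC and dACC, and
visual inflow over the four most group-discriminating rAI coefficients —
followed by a single-step multiple regression of the severity composite on
the two brain composites with antipsychotic dose as covariate.

PCA is performed on the correlation matrix (the inputs mix units: symptom
scores, years, test scores), and component signs are fixed by convention
(positive loading-weighted mean), since a principal component's sign is
otherwise arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .networks import LOOP_PAIRS, VISUAL_INFLOW_EDGES
from .simulate import SEVERITY_FLIP, SEVERITY_VARS

__all__ = [
    "FactorScores",
    "SeverityRegressionResult",
    "pc1",
    "build_composites",
    "severity_regression",
]


@dataclass
class FactorScores:
    """First principal component of a standardized variable set."""

    name: str
    variables: list[str]
    loadings: np.ndarray
    scores: np.ndarray
    variance_explained: float


@dataclass
class SeverityRegressionResult:
    """Standardized single-step multiple regression of the severity composite."""

    predictors: list[str]
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    p_model: float
    vif: np.ndarray
    collinearity_warning: bool


def pc1(table: pd.DataFrame | np.ndarray, name: str = "pc1") -> FactorScores:
    """First principal component of the correlation matrix of ``table``.

    Scores are zero-mean with unit variance; ``variance_explained`` is the
    first eigenvalue's share of the trace.  The sign is oriented so that the
    loading-weighted mean of the standardized inputs loads positively
    (i.e. the loadings sum to a non-negative value).

    Raises
    ------
    ValueError
        Naming the offending variable if one is constant.
    """
    if isinstance(table, pd.DataFrame):
        variables = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(table, dtype=float))
        variables = [f"var_{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 2:
        raise ValueError("pc1 requires at least 2 observations")
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"variable {variables[j]!r} is constant")
    Zs = (X - X.mean(axis=0)) / sd
    if p == 1:
        return FactorScores(name, variables, np.ones(1), Zs[:, 0], 1.0)
    corr = (Zs.T @ Zs) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    scores = Zs @ lead
    s = scores.std(ddof=1)
    if s > 0:
        scores = scores / s
    return FactorScores(
        name=name,
        variables=variables,
        loadings=lead,
        scores=scores,
        variance_explained=float(evals[-1] / p),
    )


def severity_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Clinical variables oriented so higher = more severe.

    The processing-speed and functioning scores are recorded with higher =
    better and are sign-flipped before entering the severity composite.
    """
    missing = [v for v in SEVERITY_VARS if v not in clinical.columns]
    if missing:
        raise ValueError(f"missing severity variables: {missing}")
    out = clinical[list(SEVERITY_VARS)].astype(float).copy()
    for v, flip in zip(SEVERITY_VARS, SEVERITY_FLIP):
        if flip:
            out[v] = -out[v]
    return out


def build_composites(
    coefficients: pd.DataFrame, clinical: pd.DataFrame
) -> dict[str, FactorScores]:
    """Severity, loop-integrity and visual-inflow composites for patients.

    Parameters
    ----------
    coefficients :
        Per-patient named coefficients: net flows ``net:SRC->DST`` for the
        three loop pairs and signed path coefficients ``beta:SRC->DST`` for
        the four visual-inflow edges.
    clinical :
        Per-patient severity variables (same row order).
    """
    loop_cols = [f"net:{a}->{b}" for a, b in LOOP_PAIRS]
    vis_cols = [f"beta:{a}->{b}" for a, b in VISUAL_INFLOW_EDGES]
    missing = [c for c in loop_cols + vis_cols if c not in coefficients.columns]
    if missing:
        raise ValueError(f"missing coefficient columns: {missing}")
    if len(coefficients) != len(clinical):
        raise ValueError("coefficients and clinical tables must align")
    return {
        "severity": pc1(severity_table(clinical), name="severity"),
        "loop": pc1(coefficients[loop_cols], name="loop"),
        "visual_inflow": pc1(coefficients[vis_cols], name="visual_inflow"),
    }


def severity_regression(
    severity: FactorScores | np.ndarray,
    loop: FactorScores | np.ndarray,
    visual: FactorScores | np.ndarray,
    dose: np.ndarray,
    vif_threshold: float = 5.0,
) -> SeverityRegressionResult:
    """Single-step OLS of severity on loop integrity, visual inflow and dose.

    All variables are standardized, so the reported coefficients are
    standardized betas.  A variance-inflation-factor check flags (but does
    not reject) collinear predictor sets.
    """
    def _scores(v):
        return v.scores if isinstance(v, FactorScores) else np.asarray(v, float)

    yv = _z(_scores(severity))
    X = np.column_stack([_z(_scores(loop)), _z(_scores(visual)), _z(np.asarray(dose, float))])
    n, k = X.shape
    if n <= 5:
        raise ValueError("severity regression requires n > 5")
    vif = np.array([_vif(X, j) for j in range(k)])
    model = sm.OLS(yv, sm.add_constant(X)).fit()
    return SeverityRegressionResult(
        predictors=["loop", "visual_inflow", "dose"],
        beta=model.params[1:],
        t=model.tvalues[1:],
        p=model.pvalues[1:],
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        p_model=float(model.f_pvalue),
        vif=vif,
        collinearity_warning=bool(np.any(vif > vif_threshold)),
    )


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _vif(X: np.ndarray, j: int) -> float:
    others = np.delete(X, j, axis=1)
    Z = np.column_stack([np.ones(X.shape[0]), others])
    beta, *_ = np.linalg.lstsq(Z, X[:, j], rcond=None)
    resid = X[:, j] - Z @ beta
    ss_res = resid @ resid
    ss_tot = ((X[:, j] - X[:, j].mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(1.0 / max(1.0 - r2, 1e-12))
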