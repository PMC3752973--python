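"""Named-region networks with estimand-calibrated lag-1 influence weights.

A :class:`NetworkSpec` is the generative analogue of a signed path coefficient
map: a stationary VAR(1) over named regions whose weights are *calibrated* so
that the population value of the bivariate lag-1 signed path coefficient —
measured by the same estimator the analysis uses, after the hemodynamic /
decimation / noise / band-pass observation chain — equals a stated target for
every named edge.  Group differences between two such networks are therefore
differences in the quantity the pipeline actually estimates, not in raw
simulator weights.

The default control/patient networks carry the published group-mean
coefficients for the salience-execution loop (rAI, rDLPFC, dACC), the visual
and hippocampal inflow to the rAI, the rAI -> precuneus outflow, and an
instantaneous rAI-temporal-pole coupling used by the functional-connectivity
and mediation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.special import gammaln

from .estimand import ObservationChain, population_edge_betas, spectral_radius

__all__ = [
    "RegionSpec",
    "HemoSpec",
    "NetworkSpec",
    "EdgeTarget",
    "double_gamma_hrf",
    "hrf_kernel",
    "calibrate_network",
    "DEFAULT_REGIONS",
    "CONTROL_EDGES",
    "PATIENT_EDGES",
    "LOOP_EDGES",
    "VISUAL_INFLOW_EDGES",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named region (parcel) of the simulated network.

    ``mni_mm`` is an optional MNI coordinate in millimetres, used only by the
    NIfTI writers to place the region's voxel block.
    """

    name: str
    role: str = "target"  # {"seed", "target", "nuisance-source"}
    mni_mm: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class HemoSpec:
    """Hemodynamic observation model.

    Parameters
    ----------
    enabled :
        If False the neural series is simulated directly at the TR and only
        decimation-free observation noise / band-pass apply.
    peak_delay_s :
        Time-to-peak of the canonical double-gamma response, seconds.
    delay_jitter_sd_s :
        SD of the per-region, per-subject random shift of the response,
        seconds.  This is the confound the diagnostic suite manipulates:
        zero-mean subject-random delays leave group-level directed effects
        null, while a delay offset that is consistent across subjects can
        masquerade as a directed influence.
    micro_dt_s :
        Micro-step of the neural simulation before convolution, seconds.
    sample_tr_s :
        Repetition time of the observed series, seconds.
    """

    enabled: bool = True
    peak_delay_s: float = 6.0
    delay_jitter_sd_s: float = 0.5
    micro_dt_s: float = 0.5
    sample_tr_s: float = 2.5

    def __post_init__(self) -> None:
        if self.peak_delay_s < 0:
            raise ValueError("peak_delay_s must be non-negative")
        if self.delay_jitter_sd_s < 0:
            raise ValueError("delay_jitter_sd_s must be non-negative")
        if self.sample_tr_s <= 0 or self.micro_dt_s <= 0:
            raise ValueError("sample_tr_s and micro_dt_s must be positive")
        if self.enabled and self.sample_tr_s % self.micro_dt_s > 1e-9:
            raise ValueError("sample_tr_s must be an integer multiple of micro_dt_s")

    @property
    def decimate(self) -> int:
        return int(round(self.sample_tr_s / self.micro_dt_s)) if self.enabled else 1


@dataclass(frozen=True)
class EdgeTarget:
    """A directed edge with its target population path coefficient.

    ``sd`` is the published between-subject SD of the estimated coefficient
    for this edge (estimation noise included); the cohort generator derives
    the true between-subject spread from it.
    """

    src: str
    dst: str
    beta: float
    sd: float | None = None


@dataclass
class NetworkSpec:
    """Calibrated VAR(1) network over named regions.

    Attributes
    ----------
    regions :
        Region roster; names must be unique.
    W :
        Signed lag-1 influence matrix: ``W[i, j]`` is the influence of region
        j on region i one TR later.  The diagonal holds autoregressive terms
        applied at the simulation step.  When the network is simulated at a
        finer micro-step (hemodynamic mode), the off-diagonal influences act
        at a lag of ``influence_lag`` micro-steps (one TR) while the diagonal
        acts at the micro-step; at the TR the two coincide and the recursion
        is the classic ``z_t = W z_{t-1} + e_t``.  The companion spectral
        radius must be < 1.
    influence_lag :
        Lag of the off-diagonal influences, in simulation steps.
    innovation_sd :
        Per-region innovation SD.
    innovation_corr :
        Pairwise innovation correlations ``{(a, b): rho}`` producing
        instantaneous (zero-lag) coupling.
    edge_targets :
        The estimand-space targets the calibration solved for.
    corr_targets :
        Zero-lag correlation targets for innovation pairs.
    sensitivity :
        Inverse Jacobian of the estimand map at the solution: maps a small
        estimand-space perturbation to the weight-space perturbation that
        realizes it.  Used as the Newton preconditioner for per-subject
        heterogeneity.
    chain :
        The observation chain the calibration solved under (None for
        hand-built networks).
    """

    regions: list[RegionSpec]
    W: np.ndarray
    innovation_sd: np.ndarray
    influence_lag: int = 1
    innovation_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    edge_targets: list[EdgeTarget] = field(default_factory=list)
    corr_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    sensitivity: np.ndarray | None = None
    chain: "ObservationChain | None" = None

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(names), len(names)):
            raise ValueError("W must be square with one row per region")
        if spectral_radius(self.W, self.influence_lag) >= 1.0:
            raise ValueError("network is not stationary: spectral radius of W >= 1")
        self.innovation_sd = np.broadcast_to(
            np.asarray(self.innovation_sd, dtype=float), (len(names),)
        ).copy()
        if np.any(self.innovation_sd <= 0):
            raise ValueError("innovation_sd must be positive")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def edge_estimand(self, src: str, dst: str) -> float:
        """Target path coefficient of a calibrated edge."""
        for e in self.edge_targets:
            if e.src == src and e.dst == dst:
                return e.beta
        raise KeyError(f"no calibrated edge {src} -> {dst}")

    def innovation_cov(self) -> np.ndarray:
        """Innovation covariance matrix implied by sds and correlations."""
        r = len(self.regions)
        Q = np.diag(self.innovation_sd**2)
        for (a, b), rho in self.innovation_corr.items():
            ia, ib = self.index(a), self.index(b)
            cov = rho * self.innovation_sd[ia] * self.innovation_sd[ib]
            Q[ia, ib] = Q[ib, ia] = cov
        return Q


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response evaluated at times ``t``.

    Two gamma densities (unit rate) with modes at ``peak_s`` and
    ``undershoot_s``; the undershoot is subtracted with weight ``ratio``.
    Zero for negative times; peak normalized to 1.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x: np.ndarray, shape: float) -> np.ndarray:
        return np.exp((shape - 1) * np.log(x) - x - gammaln(shape))

    out[pos] = gpdf(tp, peak_s + 1.0) - ratio * gpdf(tp, undershoot_s + 1.0)
    m = out.max()
    return out / m if m > 0 else out


def hrf_kernel(hemo: HemoSpec, shift_s: float = 0.0, duration_s: float = 32.0) -> np.ndarray:
    """HRF sampled at the micro-step, time-shifted by ``shift_s`` seconds."""
    t = np.arange(0.0, duration_s, hemo.micro_dt_s) - shift_s
    return double_gamma_hrf(t, peak_s=hemo.peak_delay_s)


def observation_chain(
    hemo: HemoSpec,
    obs_noise_var: float = 0.0,
    band: tuple[float, float] | None = (0.01, 0.08),
    n_freq: int = 1024,
) -> ObservationChain:
    """Observation chain matching the generator's default analysis path."""
    return ObservationChain(
        decimate=hemo.decimate,
        hrf_kernel=hrf_kernel(hemo) if hemo.enabled else None,
        obs_noise_var=obs_noise_var,
        band=band,
        tr_s=hemo.sample_tr_s,
        n_freq=n_freq,
    )


def calibrate_network(
    regions: list[RegionSpec],
    edges: list[EdgeTarget],
    chain: ObservationChain,
    corr_targets: dict[tuple[str, str], float] | None = None,
    diag: float = 0.3,
    innovation_sd: float = 1.0,
    edge_offsets: np.ndarray | None = None,
) -> NetworkSpec:
    """Solve for VAR weights whose population estimands hit the edge targets.

    Free parameters are the off-diagonal weights of the named edges and the
    innovation correlations of the named pairs; the residual is the gap
    between the chain's population path coefficients / zero-lag correlations
    and their targets.  ``edge_offsets`` shifts the beta targets (used by the
    finite-sample refinement).

    Raises
    ------
    RuntimeError
        If the root search does not converge.
    """
    corr_targets = dict(corr_targets or {})
    names = [r.name for r in regions]
    r = len(names)
    idx = {n: i for i, n in enumerate(names)}
    edge_ix = [(idx[e.src], idx[e.dst]) for e in edges]
    pair_ix = [(idx[a], idx[b]) for a, b in corr_targets]
    beta_targets = np.array([e.beta for e in edges])
    if edge_offsets is not None:
        beta_targets = beta_targets + np.asarray(edge_offsets, dtype=float)
    targets = np.concatenate([beta_targets, np.array(list(corr_targets.values()))])
    ne = len(edges)

    def build(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W = np.eye(r) * diag
        for (s, d), w in zip(edge_ix, params[:ne]):
            W[d, s] = w
        Q = np.eye(r) * innovation_sd**2
        for (a, b), q in zip(pair_ix, params[ne:]):
            Q[a, b] = Q[b, a] = q * innovation_sd**2
        return W, Q

    def residual(params: np.ndarray) -> np.ndarray:
        W, Q = build(params)
        if spectral_radius(W, chain.decimate) >= 0.99:
            return np.full_like(targets, 10.0)
        got = population_edge_betas(W, Q, edge_ix, chain, pair_ix)
        return got - targets

    sol = root(residual, x0=targets.copy(), method="hybr", tol=1e-10)
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-6:
        raise RuntimeError(f"network calibration did not converge: {sol.message}")

    # Sensitivity of parameters to estimand-space perturbations, for
    # per-subject heterogeneity: d params / d targets = J^{-1}.
    n_par = targets.size
    J = np.empty((n_par, n_par))
    h = 1e-4
    base = residual(sol.x)
    for j in range(n_par):
        p = sol.x.copy()
        p[j] += h
        J[:, j] = (residual(p) - base) / h
    sens = np.linalg.inv(J)

    W, _ = build(sol.x)
    return NetworkSpec(
        regions=list(regions),
        W=W,
        innovation_sd=np.full(r, float(innovation_sd)),
        influence_lag=chain.decimate,
        innovation_corr={
            pair: float(q) for pair, q in zip(corr_targets, sol.x[ne:])
        },
        edge_targets=list(edges),
        corr_targets=corr_targets,
        sensitivity=sens,
        chain=chain,
    )


def _network_params(net: NetworkSpec) -> np.ndarray:
    """Current free parameters: calibrated edge weights, then innovation corrs."""
    idx = {n: i for i, n in enumerate(net.names)}
    ws = [net.W[idx[e.dst], idx[e.src]] for e in net.edge_targets]
    return np.array(ws + list(net.innovation_corr.values()))


def _apply_params(net: NetworkSpec, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(W, Q) with the free parameters replaced by ``params``."""
    idx = {n: i for i, n in enumerate(net.names)}
    ne = len(net.edge_targets)
    W = net.W.copy()
    for k, e in enumerate(net.edge_targets):
        W[idx[e.dst], idx[e.src]] = params[k]
    Q = np.diag(net.innovation_sd**2)
    for (a, b), rho in zip(net.innovation_corr, params[ne:]):
        ia, ib = idx[a], idx[b]
        Q[ia, ib] = Q[ib, ia] = rho * net.innovation_sd[ia] * net.innovation_sd[ib]
    return W, Q


def solve_subject_network(
    net: NetworkSpec,
    edge_deltas: np.ndarray,
    corr_deltas: np.ndarray,
    max_radius: float = 0.97,
    tol: float = 2e-4,
    max_iter: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """(W, Q) of a subject whose estimands are the group targets plus deltas.

    Runs a damped quasi-Newton iteration on the calibrated network's
    estimand map, preconditioned with the stored inverse Jacobian.  If a
    requested perturbation is unreachable inside the stability region (the
    estimand saturates as the companion radius approaches 1), the deltas are
    shrunk geometrically until the solve succeeds — a symmetric truncation
    of extreme subjects that leaves the population mean untouched.

    For networks without calibration metadata the deltas are added to the
    corresponding weights directly.
    """
    edge_deltas = np.asarray(edge_deltas, dtype=float)
    corr_deltas = np.asarray(corr_deltas, dtype=float)
    idx = {n: i for i, n in enumerate(net.names)}
    if net.chain is None or net.sensitivity is None:
        W = net.W.copy()
        for k, e in enumerate(net.edge_targets):
            W[idx[e.dst], idx[e.src]] += edge_deltas[k]
        corr = np.clip(
            np.array(list(net.innovation_corr.values())) + corr_deltas, -0.95, 0.95
        )
        _, Q = _apply_params(net, np.concatenate([
            [W[idx[e.dst], idx[e.src]] for e in net.edge_targets], corr
        ]))
        return W, Q

    chain = net.chain
    edge_ix = [(idx[e.src], idx[e.dst]) for e in net.edge_targets]
    pair_ix = [(idx[a], idx[b]) for a, b in net.corr_targets]
    base = np.array(
        [e.beta for e in net.edge_targets] + list(net.corr_targets.values())
    )
    p0 = _network_params(net)
    ne = len(net.edge_targets)

    for shrink in (1.0, 0.7, 0.5, 0.3, 0.15, 0.0):
        delta = shrink * np.concatenate([edge_deltas, corr_deltas])
        targets = base + delta
        p = p0 + net.sensitivity @ delta  # linear warm start
        ok = False
        for _ in range(max_iter):
            W, Q = _apply_params(net, p)
            if (spectral_radius(W, net.influence_lag) >= max_radius
                    or np.any(np.abs(p[ne:]) >= 0.98)):
                break
            r = population_edge_betas(W, Q, edge_ix, chain, pair_ix) - targets
            if np.max(np.abs(r)) < tol:
                ok = True
                break
            p = p - 0.9 * (net.sensitivity @ r)
        if ok:
            return _apply_params(net, p)
    return _apply_params(net, p0)


# ---------------------------------------------------------------------------
# Default roster and published group-mean edge coefficients.
# ---------------------------------------------------------------------------

DEFAULT_REGIONS: list[RegionSpec] = [
    RegionSpec("rAI", role="seed", mni_mm=(33.0, 21.0, -3.0)),
    RegionSpec("rDLPFC", mni_mm=(48.0, 34.0, 24.0)),
    RegionSpec("dACC", mni_mm=(2.0, 18.0, 30.0)),
    RegionSpec("precuneus", mni_mm=(-4.0, -70.0, 32.0)),
    RegionSpec("lCuneus", mni_mm=(-18.0, -92.0, 22.0)),
    RegionSpec("rCuneus", mni_mm=(24.0, -90.0, 16.0)),
    RegionSpec("rHippocampus", mni_mm=(32.0, -8.0, -16.0)),
    RegionSpec("rTemporalPole", mni_mm=(44.0, 14.0, -24.0)),
]

# Published group means (SDs) of the signed path coefficients (control,
# patient) for the edges the study reports; the two unreported loop closures
# (rAI <-> dACC) carry qualitative one-sample signs shared by both groups.
_EDGE_TABLE: list[tuple[str, str, float, float, float, float]] = [
    ("rAI", "rDLPFC", 0.103, 0.08, 0.027, 0.08),
    ("rAI", "precuneus", 0.072, 0.14, -0.039, 0.10),
    ("lCuneus", "rAI", 0.045, 0.05, -0.035, 0.09),
    ("rCuneus", "rAI", 0.034, 0.05, -0.030, 0.08),
    ("rHippocampus", "rAI", 0.031, 0.07, -0.025, 0.05),
    ("rDLPFC", "rAI", -0.052, 0.06, 0.013, 0.07),
    ("dACC", "rDLPFC", 0.068, 0.05, 0.001, 0.05),
    ("rDLPFC", "dACC", -0.079, 0.06, -0.009, 0.06),
    ("dACC", "rAI", -0.050, 0.07, -0.050, 0.07),
    ("rAI", "dACC", 0.030, 0.07, 0.030, 0.07),
]

CONTROL_EDGES: list[EdgeTarget] = [
    EdgeTarget(s, d, c, cs) for s, d, c, cs, _, _ in _EDGE_TABLE
]
PATIENT_EDGES: list[EdgeTarget] = [
    EdgeTarget(s, d, p, ps) for s, d, _, _, p, ps in _EDGE_TABLE
]

# Zero-lag (innovation) coupling between rAI and the temporal pole: the
# published group-mean Pearson correlation of the FC contrast cluster.
CONTROL_CORR: dict[tuple[str, str], float] = {("rAI", "rTemporalPole"): 0.211}
PATIENT_CORR: dict[tuple[str, str], float] = {("rAI", "rTemporalPole"): 0.005}

# Edges entering the salience-execution loop composite (net flows among
# rAI, rDLPFC, dACC) and the visual/hippocampal inflow composite.
LOOP_PAIRS: list[tuple[str, str]] = [
    ("rAI", "rDLPFC"),
    ("rAI", "dACC"),
    ("dACC", "rDLPFC"),
]
LOOP_EDGES: list[tuple[str, str]] = [
    ("rAI", "rDLPFC"),
    ("rDLPFC", "rAI"),
    ("rAI", "dACC"),
    ("dACC", "rAI"),
    ("dACC", "rDLPFC"),
    ("rDLPFC", "dACC"),
]
VISUAL_INFLOW_EDGES: list[tuple[str, str]] = [
    ("rAI", "precuneus"),
    ("lCuneus", "rAI"),
    ("rCuneus", "rAI"),
    ("rHippocampus", "rAI"),
]
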