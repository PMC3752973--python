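"""Synthetic two-group resting-state cohorts with known directed influences.

The generator emulates the study conditions the downstream pipeline was built
for: ~35 control and ~38 patient subjects, parcel time series at TR 2.5 s,
band-limited neural dynamics with signed lag-1 directed influences among
named regions, canonical hemodynamic convolution with per-subject/per-region
delay jitter, shared nuisance signals, observation noise, and a clinical
table whose correlation structure matches the published summaries.

Ground truth is carried along at every level: each subject records the
estimand-space path coefficients it was generated with, the latent loop /
visual / connectivity factors that couple brain measures to the clinical
variables, and the sampled hemodynamic delays.  Seeded runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.signal import fftconvolve

from .estimand import spectral_radius
from .networks import (
    CONTROL_CORR,
    CONTROL_EDGES,
    DEFAULT_REGIONS,
    LOOP_EDGES,
    PATIENT_CORR,
    PATIENT_EDGES,
    VISUAL_INFLOW_EDGES,
    EdgeTarget,
    HemoSpec,
    NetworkSpec,
    calibrate_network,
    hrf_kernel,
    observation_chain,
    solve_subject_network,
)

__all__ = [
    "ClinicalSpec",
    "CohortConfig",
    "SubjectData",
    "build_default_networks",
    "simulate_neural",
    "apply_hemodynamics",
    "simulate_clinical",
    "simulate_cohort",
    "clinical_correlation_matrix",
]

BURN_IN_STEPS = 100

#: Default six severity variables: three symptom-domain scores, duration of
#: illness, a processing-speed score and a social/occupational functioning
#: score.  The last two are scored so that *higher is better* and are
#: sign-flipped before entering the severity composite.
SEVERITY_VARS = (
    "sspi_reality_distortion",
    "sspi_disorganization",
    "sspi_psychomotor_poverty",
    "duration_illness_years",
    "dsst_score",
    "sofas_score",
)
_SEVERITY_MEANS = (4.0, 4.0, 4.1, 8.0, 50.0, 55.0)
_SEVERITY_SDS = (2.4, 2.4, 2.4, 6.0, 12.0, 12.0)
#: Variables where higher raw scores mean *less* severe illness.
SEVERITY_FLIP = (False, False, False, False, True, True)


@dataclass(frozen=True)
class ClinicalSpec:
    """Generator for the patient clinical table.

    ``target_mean_abs_corr`` is the mean absolute pairwise correlation of the
    six severity variables; ``target_pc1_share`` the fraction of variance
    their first principal component explains.  Both are population targets
    the variable correlation matrix is calibrated to (a mean |r| of 0.34
    with only 40% first-component variance requires sign-frustrated
    correlations; see :func:`clinical_correlation_matrix`).

    ``severity_loop_coupling`` / ``severity_visual_coupling`` are the
    standardized effects of the latent loop-integrity and visual-inflow
    factors on the latent severity factor (negative: more integrity, less
    severity).  ``dose_coupling`` correlates antipsychotic dose with latent
    severity (positive: sicker patients are prescribed more).
    """

    severity_var_names: tuple[str, ...] = SEVERITY_VARS
    target_mean_abs_corr: float = 0.34
    target_pc1_share: float | None = 0.40
    severity_loop_coupling: float = -0.45
    severity_visual_coupling: float = -0.20
    dose_coupling: float = 0.25
    dose_mean: float = 400.0
    dose_sd: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_mean_abs_corr < 1.0:
            raise ValueError("target_mean_abs_corr must lie in (0, 1)")
        if len(self.severity_var_names) != 6:
            raise ValueError("expected six severity variables")
        tot = self.severity_loop_coupling**2 + self.severity_visual_coupling**2
        if tot >= 1.0:
            raise ValueError("squared severity couplings must sum to < 1")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated cohort.

    Defaults reproduce the emulated study: 35 controls, 38 patients, 300
    retained volumes (~12.5 min at TR 2.5 s) after 5 discarded ones,
    hemodynamic observation with 6 s peak and 0.5 s per-region/subject delay
    jitter, nuisance and observation noise at about half resp. a third of
    the unit signal scale, and a between-subject SD of the true edge
    coefficients of 0.05 (so that together with estimation noise the
    observed per-subject spread lands near the published 0.08).
    """

    n_controls: int = 35
    n_patients: int = 38
    n_timepoints: int = 300
    n_discard: int = 5
    networks: dict[str, NetworkSpec] | None = None
    hemo: HemoSpec = field(default_factory=HemoSpec)
    nuisance_sd: float = 0.5
    observation_noise_sd: float = 0.3
    band: tuple[float, float] = (0.01, 0.08)
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    between_subject_sd: float = 0.05
    #: Estimation-noise SD assumed when converting a published per-edge
    #: coefficient SD into the true between-subject spread:
    #: ``between^2 = max(published^2 - assumed^2, 0)``.
    assumed_estimation_sd: float = 0.06
    shared_latent_frac: float = 0.6
    #: Between-subject SD of the seed-temporal-pole coupling (the published
    #: FC SDs of 0.13-0.18 include ~0.1 of estimation noise).
    fc_subject_sd: float = 0.13
    #: Estimand-units shift of the rAI->rDLPFC coefficient per SD of the
    #: subject's (group-centered) rAI-temporal-pole coupling: the generative
    #: indirect pathway of the mediation analysis.  The default makes the
    #: mediated share of the group effect 30%.
    mediation_slope: float = 0.111
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"control": 33.5, "patient": 34.5}
    )
    age_sd: float = 9.1
    female_frac: dict[str, float] = field(
        default_factory=lambda: {"control": 10 / 35, "patient": 9 / 38}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_patients, self.n_timepoints) <= 0:
            raise ValueError("cohort counts must be positive")


@dataclass
class SubjectData:
    """One subject: region x time series, design covariates, ground truth."""

    id: str
    group: str  # {"control", "patient"}
    series: np.ndarray  # timepoints x regions, signal units
    regions: list[str]
    age: float
    gender: str  # {"F", "M"}
    dose: float
    clinical: dict[str, float] = field(default_factory=dict)
    confounds: np.ndarray | None = None
    confound_names: tuple[str, ...] = ()
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if not np.isfinite(self.series).all():
            raise ValueError("series must not contain missing values")
        if self.series.shape[1] != len(self.regions):
            raise ValueError("series columns must match region names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.series, columns=self.regions)


# ---------------------------------------------------------------------------
# Neural dynamics and hemodynamic observation
# ---------------------------------------------------------------------------


def _simulate_neural_batch(
    W: np.ndarray,
    Q: np.ndarray,
    n_timepoints: int,
    n_subjects: int,
    rng: np.random.Generator,
    influence_lag: int = 1,
    burn_in: int = BURN_IN_STEPS,
) -> np.ndarray:
    """Simulate ``n_subjects`` independent runs of the (two-lag) VAR.

    Returns an array of shape (n_subjects, n_timepoints, n_regions).
    """
    W = np.asarray(W, dtype=float)
    L = int(influence_lag)
    if spectral_radius(W, L) >= 1.0:
        raise ValueError("VAR is not stationary: spectral radius >= 1")
    r = W.shape[0]
    d = np.diag(W)
    B = W - np.diag(d)
    total = n_timepoints + burn_in + L
    chol = np.linalg.cholesky(Q + 1e-15 * np.eye(r))
    e = rng.standard_normal((total, n_subjects, r)) @ chol.T
    z = np.zeros((total, n_subjects, r))
    for t in range(1, total):
        z[t] = d * z[t - 1] + e[t]
        if t >= L:
            z[t] += z[t - L] @ B.T
    return np.swapaxes(z[burn_in + L:], 0, 1)


def simulate_neural(
    net: NetworkSpec,
    n_timepoints: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's neural series ``z_t = W z_{t-1} + e_t`` (timepoints x regions).

    Innovations are Gaussian with the network's per-region SDs and
    correlations; a burn-in of 100 steps is discarded so initial-condition
    effects are negligible.
    """
    return _simulate_neural_batch(
        net.W, net.innovation_cov(), n_timepoints, 1, rng,
        influence_lag=net.influence_lag,
    )[0]


def apply_hemodynamics(
    neural: np.ndarray,
    hemo: HemoSpec,
    rng: np.random.Generator | None = None,
    delays_s: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve each region with a delayed canonical response and decimate.

    Parameters
    ----------
    neural :
        Micro-step series (timepoints x regions) sampled at
        ``hemo.micro_dt_s`` (or at the TR when ``hemo.enabled`` is False,
        in which case the input is returned decimated only, i.e. unchanged
        for decimation factor 1).
    delays_s :
        Per-region response delays in seconds; sampled as
        ``N(peak_delay_s, delay_jitter_sd_s)`` when omitted.

    The convolution transient (one kernel length) is discarded before
    decimation, so the output is shorter than ``len(neural) / decimate``.
    """
    neural = np.atleast_2d(np.asarray(neural, dtype=float))
    m = hemo.decimate
    if not hemo.enabled:
        return neural[::1].copy()
    n_t, n_r = neural.shape
    if delays_s is None:
        if rng is None:
            rng = np.random.default_rng()
        delays_s = rng.normal(hemo.peak_delay_s, hemo.delay_jitter_sd_s, size=n_r)
    delays_s = np.asarray(delays_s, dtype=float)
    if np.any(delays_s < 0):
        raise ValueError("hemodynamic delays must be non-negative")
    kernels = [hrf_kernel(hemo, shift_s=d - hemo.peak_delay_s) for d in delays_s]
    klen = kernels[0].size
    out = np.empty((n_t - klen, n_r))
    for i in range(n_r):
        conv = fftconvolve(neural[:, i], kernels[i])[:n_t]
        out[:, i] = conv[klen:]
    return out[::m].copy()


# ---------------------------------------------------------------------------
# Clinical variables
# ---------------------------------------------------------------------------

# Symmetric conference-matrix sign pattern (S @ S.T = 5 I): the maximally
# frustrated 6-variable sign structure, blended with the aligned all-plus
# pattern to reach first-component shares below the aligned bound.
_CONFERENCE_SIGNS = np.array(
    [
        [0, 1, 1, 1, 1, 1],
        [1, 0, 1, -1, -1, 1],
        [1, 1, 0, 1, -1, -1],
        [1, -1, 1, 0, 1, -1],
        [1, -1, -1, 1, 0, 1],
        [1, 1, -1, -1, 1, 0],
    ],
    dtype=float,
)


def clinical_correlation_matrix(spec: ClinicalSpec) -> np.ndarray:
    """Population correlation matrix of the six severity variables.

    With only a mean-|r| target the matrix is equicorrelated.  When a
    first-component variance share is also targeted, the matrix is a blend
    ``I + a J_off + b S`` of the aligned pattern and a conference-matrix
    sign pattern, with (a, b) solved so both targets hold: alignable
    correlations bound the first-eigenvalue share from below at
    ``(1 + 5 r̄)/6``, so shares below that bound require frustrated signs.
    """
    r_bar = spec.target_mean_abs_corr
    if spec.target_pc1_share is None:
        return np.eye(6) * (1 - r_bar) + r_bar

    share = spec.target_pc1_share
    j_off = np.ones((6, 6)) - np.eye(6)
    pairs = np.triu_indices(6, 1)

    def build(params: np.ndarray) -> np.ndarray:
        a, b = params
        return np.eye(6) + a * j_off + b * _CONFERENCE_SIGNS

    def resid(params: np.ndarray) -> np.ndarray:
        C = build(params)
        ev = np.linalg.eigvalsh(C)
        return np.array([
            np.abs(C[pairs]).mean() - r_bar,
            ev[-1] / 6.0 - share,
        ])

    sol = root(resid, x0=np.array([r_bar * 0.6, r_bar * 0.5]), method="hybr")
    C = build(sol.x)
    if (not sol.success or np.max(np.abs(resid(sol.x))) > 1e-8
            or np.linalg.eigvalsh(C)[0] <= 1e-6):
        raise ValueError(
            f"no valid correlation structure for mean |r|={r_bar}, "
            f"first-component share={share}"
        )
    return C


def simulate_clinical(
    loop_scores: np.ndarray,
    spec: ClinicalSpec,
    rng: np.random.Generator,
    visual_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Six severity variables for one patient group.

    A latent severity factor is built from the standardized loop-integrity
    scores (and optionally visual-inflow scores) with the configured
    couplings plus independent noise; the six variables are generated so
    their population correlation matrix is :func:`clinical_correlation_matrix`
    with the severity factor aligned to the first principal component.
    Variables are returned in interpretable units; the processing-speed and
    functioning scores are oriented so higher = better.

    The latent factor is stored in ``DataFrame.attrs["severity_latent"]``;
    ``attrs["dose_z"]`` holds a standardized dose aligned with severity at
    ``spec.dose_coupling``.
    """
    loop = np.asarray(loop_scores, dtype=float).ravel()
    n = loop.size
    loop = (loop - loop.mean()) / loop.std() if n > 1 and loop.std() > 0 else loop
    cl = spec.severity_loop_coupling
    cv = spec.severity_visual_coupling
    if visual_scores is None:
        vis = np.zeros(n)
        cv = 0.0
    else:
        vis = np.asarray(visual_scores, dtype=float).ravel()
        if n > 1 and vis.std() > 0:
            vis = (vis - vis.mean()) / vis.std()
    resid_sd = np.sqrt(max(1.0 - cl**2 - cv**2, 0.0))
    severity = cl * loop + cv * vis + resid_sd * rng.standard_normal(n)

    C = clinical_correlation_matrix(spec)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # orient PC1 toward "more severe on the flipped scale"
    signs = np.where(SEVERITY_FLIP, -1.0, 1.0)
    if (evecs[:, 0] * signs).sum() < 0:
        evecs[:, 0] = -evecs[:, 0]
    g = rng.standard_normal((n, 6))
    g[:, 0] = severity
    vals = g @ (evecs * np.sqrt(np.clip(evals, 0, None))).T

    data = {}
    for j, name in enumerate(spec.severity_var_names):
        v = vals[:, j]
        if SEVERITY_FLIP[j]:
            v = -v
        data[name] = _SEVERITY_MEANS[j] + _SEVERITY_SDS[j] * v
    out = pd.DataFrame(data)
    dc = spec.dose_coupling
    out.attrs["severity_latent"] = severity
    out.attrs["dose_z"] = dc * severity + np.sqrt(1 - dc**2) * rng.standard_normal(n)
    return out


# ---------------------------------------------------------------------------
# Default networks with finite-sample refinement
# ---------------------------------------------------------------------------

_NETWORK_CACHE: dict[tuple, dict[str, NetworkSpec]] = {}


def build_default_networks(
    hemo: HemoSpec | None = None,
    observation_noise_sd: float = 0.3,
    band: tuple[float, float] | None = (0.01, 0.08),
    n_timepoints: int | None = 300,
    refine_subjects: int = 2000,
) -> dict[str, NetworkSpec]:
    """Control and patient networks calibrated to the published coefficients.

    Weights are solved so the population path coefficient recovered by the
    lag-1 estimator — through hemodynamic convolution, decimation to the TR,
    observation noise and the band mask — equals the published group means
    for every named edge, and the population zero-lag rAI-temporal-pole
    correlation equals the published FC means.  When ``n_timepoints`` is
    given, a deterministic Monte-Carlo refinement (internal fixed seed,
    ``refine_subjects`` simulated subjects) absorbs the residual
    finite-sample bias of the estimator at that series length.

    Results are cached per parameter set.
    """
    hemo = hemo or HemoSpec()
    key = (hemo, observation_noise_sd, band, n_timepoints, refine_subjects)
    if key in _NETWORK_CACHE:
        return _NETWORK_CACHE[key]
    chain = observation_chain(hemo, obs_noise_var=observation_noise_sd**2, band=band)
    nets: dict[str, NetworkSpec] = {}
    for group, edges, corr in (
        ("control", CONTROL_EDGES, CONTROL_CORR),
        ("patient", PATIENT_EDGES, PATIENT_CORR),
    ):
        net = calibrate_network(DEFAULT_REGIONS, edges, chain, corr)
        if n_timepoints:
            bias = _finite_sample_bias(
                net, hemo, observation_noise_sd, band, n_timepoints,
                refine_subjects,
            )
            if np.max(np.abs(bias)) > 1e-3:
                net = calibrate_network(
                    DEFAULT_REGIONS, edges, chain, corr, edge_offsets=-bias
                )
        nets[group] = net
    _NETWORK_CACHE[key] = nets
    return nets


def _finite_sample_bias(
    net: NetworkSpec,
    hemo: HemoSpec,
    obs_sd: float,
    band: tuple[float, float] | None,
    n_timepoints: int,
    n_subjects: int,
) -> np.ndarray:
    """Mean estimator bias per calibrated edge at finite series length.

    Simulates ``n_subjects`` subjects through the full generation +
    conditioning + estimation path (fixed internal seed) and returns the
    mean estimated coefficient minus the calibration target per edge.
    """
    from .connectivity import pairwise_gca
    from .preprocess import PreprocConfig, preprocess_series

    rng = np.random.default_rng(987654321)
    m = hemo.decimate
    klen = hrf_kernel(hemo).size if hemo.enabled else 0
    n_keep = n_timepoints
    n_micro = n_keep * m + klen + m
    series = _simulate_neural_batch(
        net.W, net.innovation_cov(), n_micro, n_subjects, rng,
        influence_lag=net.influence_lag,
    )
    cfg = PreprocConfig(
        discard_initial=0,
        band_low_hz=band[0] if band else 0.0,
        band_high_hz=band[1] if band else 1.0 / (2 * hemo.sample_tr_s),
        tr_s=hemo.sample_tr_s,
    )
    idx = {n: i for i, n in enumerate(net.names)}
    sums = np.zeros(len(net.edge_targets))
    for s in range(n_subjects):
        obs = apply_hemodynamics(series[s], hemo, rng)[:n_keep]
        obs = obs / obs.std(axis=0, ddof=1)
        obs = obs + obs_sd * rng.standard_normal(obs.shape)
        obs = preprocess_series(obs, cfg)
        cache: dict[tuple[int, int], tuple[float, float]] = {}
        for k, e in enumerate(net.edge_targets):
            a, b = idx[e.src], idx[e.dst]
            pair = (a, b) if a < b else (b, a)
            if pair not in cache:
                cache[pair] = pairwise_gca(obs[:, pair[0]], obs[:, pair[1]])
            bxy, byx = cache[pair]
            sums[k] += bxy if a == pair[0] else byx
    means = sums / n_subjects
    return means - np.array([e.beta for e in net.edge_targets])


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

_CONFOUND_NAMES = tuple(f"motion_{i}" for i in range(6)) + (
    "global_signal", "drift_linear", "drift_slow",
)


def _nuisance_channels(n_t: int, rng: np.random.Generator) -> np.ndarray:
    """Nine standardized nuisance channels: 6 pseudo-motion AR(1) series,
    a slow global component, a linear drift and a slow sinusoid."""
    ch = np.empty((n_t, 9))
    for i in range(6):
        ch[:, i] = _ar1(n_t, 0.95, rng)
    ch[:, 6] = _ar1(n_t, 0.8, rng)
    ch[:, 7] = np.linspace(-1.0, 1.0, n_t)
    ch[:, 8] = np.sin(np.linspace(0, 3 * np.pi, n_t) + rng.uniform(0, 2 * np.pi))
    sd = ch.std(axis=0, ddof=1)
    return ch / np.where(sd > 0, sd, 1.0)


def _ar1(n: int, a: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n + 50)
    z = np.empty_like(e)
    z[0] = e[0]
    for t in range(1, e.size):
        z[t] = a * z[t - 1] + np.sqrt(1 - a**2) * e[t]
    return z[50:]


def simulate_cohort(cfg: CohortConfig) -> list[SubjectData]:
    """Generate the full two-group cohort described by ``cfg``.

    Per subject: latent loop-integrity, visual-inflow and connectivity
    factors perturb the group network in estimand space (via the calibrated
    sensitivity), the neural VAR is simulated at the micro-step, observed
    through the hemodynamic chain with jittered delays, standardized, and
    contaminated with shared nuisance channels and white observation noise.
    Ages, genders, antipsychotic dose and the clinical table follow the
    published summaries.  Deterministic given ``cfg.rng_seed``.
    """
    nets = cfg.networks or build_default_networks(
        hemo=cfg.hemo,
        observation_noise_sd=cfg.observation_noise_sd,
        band=cfg.band,
        n_timepoints=cfg.n_timepoints,
    )
    ctrl_net, pat_net = nets["control"], nets["patient"]
    groups = ["control"] * cfg.n_controls + ["patient"] * cfg.n_patients
    n_total = len(groups)
    root_ss = np.random.SeedSequence(cfg.rng_seed)
    subj_seeds = root_ss.spawn(n_total)
    rng_cohort = np.random.default_rng(root_ss.spawn(1)[0])

    m = cfg.hemo.decimate
    klen = hrf_kernel(cfg.hemo).size if cfg.hemo.enabled else 0
    n_keep = cfg.n_timepoints + cfg.n_discard
    n_micro = n_keep * m + klen + m

    # group-mean betas for orienting the integrity direction
    pat_by_edge = {(e.src, e.dst): e.beta for e in pat_net.edge_targets}
    ctrl_by_edge = {(e.src, e.dst): e.beta for e in ctrl_net.edge_targets}
    loop_set = set(LOOP_EDGES)
    visual_set = set(VISUAL_INFLOW_EDGES)

    def _between_sd(e: EdgeTarget) -> float:
        if e.sd is None:
            return cfg.between_subject_sd
        return float(np.sqrt(max(e.sd**2 - cfg.assumed_estimation_sd**2, 0.0)))

    def _integrity_sign(key, rev=None) -> float:
        """Group-independent orientation: positive latent = control-like.

        For a bidirectional pair, the sign of the control-minus-patient net
        flow difference (falling back to the control net-flow direction when
        the groups do not differ); for a single edge, the sign of the
        control-minus-patient coefficient difference.
        """
        if rev is None:
            gap = ctrl_by_edge[key] - pat_by_edge[key]
            return 1.0 if gap >= 0 else -1.0
        gap = (ctrl_by_edge[key] - pat_by_edge[key]) - (
            ctrl_by_edge[rev] - pat_by_edge[rev]
        )
        if gap == 0.0:
            gap = ctrl_by_edge[key] - ctrl_by_edge[rev]
        return 1.0 if gap >= 0 else -1.0

    subjects: list[SubjectData] = []
    latents_by_group: dict[str, dict[str, list[float]]] = {
        "control": {"loop": [], "visual": [], "fc": []},
        "patient": {"loop": [], "visual": [], "fc": []},
    }
    for i, group in enumerate(groups):
        rng = np.random.default_rng(subj_seeds[i])
        net = ctrl_net if group == "control" else pat_net

        # latent factors
        loop_l = rng.standard_normal()
        vis_l = rng.standard_normal()
        fc_l = rng.standard_normal()
        phi = cfg.shared_latent_frac
        edge_index = {(e.src, e.dst): k for k, e in enumerate(net.edge_targets)}
        edge_deltas = np.zeros(len(net.edge_targets))
        done: set[tuple[str, str]] = set()
        for k, e in enumerate(net.edge_targets):
            key = (e.src, e.dst)
            if key in done:
                continue
            rev = (e.dst, e.src)
            if rev in edge_index:
                # Bidirectionally calibrated pair: the observation chain makes
                # the symmetric perturbation of such a pair nearly invisible
                # to the estimator, so subject variation is placed on the
                # antisymmetric (net-flow) mode, with amplitude the RMS of
                # the two per-edge spreads and sign following the group net
                # difference (more latent integrity = more control-like).
                kr = edge_index[rev]
                er = net.edge_targets[kr]
                amp = np.sqrt((_between_sd(e)**2 + _between_sd(er)**2) / 2.0)
                d = _integrity_sign(key, rev)
                in_loop = key in loop_set or rev in loop_set
                latent = loop_l if in_loop else 0.0
                phi_e = phi if in_loop else 0.0
                z = (np.sqrt(phi_e) * latent * d
                     + np.sqrt(1 - phi_e) * rng.standard_normal())
                edge_deltas[k] += amp * z
                edge_deltas[kr] -= amp * z
                done.add(rev)
            else:
                orient = _integrity_sign(key)
                shared = vis_l * orient if key in visual_set else 0.0
                phi_e = phi if shared != 0.0 else 0.0
                edge_deltas[k] += _between_sd(e) * (
                    np.sqrt(phi_e) * shared
                    + np.sqrt(1 - phi_e) * rng.standard_normal()
                )
            done.add(key)
        # generative indirect pathway: subject FC coupling shifts the
        # seed -> DLPFC net-flow mode (only for networks carrying that edge)
        if ("rAI", "rDLPFC") in edge_index:
            med = cfg.mediation_slope * cfg.fc_subject_sd * fc_l
            edge_deltas[edge_index[("rAI", "rDLPFC")]] += med
            if ("rDLPFC", "rAI") in edge_index:
                edge_deltas[edge_index[("rDLPFC", "rAI")]] -= med
        truth_edges = {
            f"{e.src}->{e.dst}": e.beta + edge_deltas[k]
            for k, e in enumerate(net.edge_targets)
        }
        corr_deltas = np.full(len(net.corr_targets), cfg.fc_subject_sd * fc_l)

        W_s, Q_s = solve_subject_network(net, edge_deltas, corr_deltas)
        corr_s = [
            Q_s[net.index(a), net.index(b)]
            / (net.innovation_sd[net.index(a)] * net.innovation_sd[net.index(b)])
            for a, b in net.corr_targets
        ]

        neural = _simulate_neural_batch(
            W_s, Q_s, n_micro, 1, rng, influence_lag=net.influence_lag
        )[0]
        delays = rng.normal(
            cfg.hemo.peak_delay_s, cfg.hemo.delay_jitter_sd_s, size=len(net.names)
        ).clip(min=0.0)
        obs = apply_hemodynamics(neural, cfg.hemo, delays_s=delays)[:n_keep]
        sd = obs.std(axis=0, ddof=1)
        obs = obs / np.where(sd > 0, sd, 1.0)

        conf = _nuisance_channels(n_keep, rng)
        load = np.zeros((9, len(net.names)))
        load[:6] = rng.normal(0.0, 0.3, size=(6, len(net.names)))
        load[6] = 1.0
        load[7:] = rng.normal(0.0, 0.5, size=(2, len(net.names)))
        obs = obs + cfg.nuisance_sd * (conf @ load)
        obs = obs + cfg.observation_noise_sd * rng.standard_normal(obs.shape)

        age = float(rng.normal(cfg.age_mean[group], cfg.age_sd))
        gender = "F" if rng.uniform() < cfg.female_frac[group] else "M"
        subjects.append(
            SubjectData(
                id=f"{'ctl' if group == 'control' else 'pat'}{i:03d}",
                group=group,
                series=obs,
                regions=net.names,
                age=age,
                gender=gender,
                dose=0.0,
                confounds=conf,
                confound_names=_CONFOUND_NAMES,
                truth={
                    "edges": truth_edges,
                    "loop_latent": loop_l,
                    "visual_latent": vis_l,
                    "fc_latent": fc_l,
                    "fc_corr": dict(zip(
                        [f"{a}~{b}" for a, b in net.corr_targets], corr_s
                    )),
                    "delays_s": delays.tolist(),
                },
            )
        )
        latents_by_group[group]["loop"].append(loop_l)
        latents_by_group[group]["visual"].append(vis_l)
        latents_by_group[group]["fc"].append(fc_l)

    # clinical table for patients
    patients = [s for s in subjects if s.group == "patient"]
    loop_scores = np.array(latents_by_group["patient"]["loop"])
    vis_scores = np.array(latents_by_group["patient"]["visual"])
    table = simulate_clinical(
        loop_scores, cfg.clinical, rng_cohort, visual_scores=vis_scores
    )
    dose_z = table.attrs["dose_z"]
    for j, subj in enumerate(patients):
        subj.clinical = {c: float(table[c].iloc[j]) for c in table.columns}
        subj.dose = float(
            max(cfg.clinical.dose_mean + cfg.clinical.dose_sd * dose_z[j], 0.0)
        )
        subj.truth["severity_latent"] = float(table.attrs["severity_latent"][j])
    return subjects


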