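"""Population values of the lag-1 signed path coefficient under a VAR generator.

The bivariate first-order Granger estimator regresses the standardized present
of a target series on the standardized lag-1 past of itself and of a source
series.  When the underlying neural dynamics are a stationary VAR(1) observed
through a linear chain (hemodynamic convolution at a fine micro-step,
decimation to the scan TR, additive observation noise, an ideal band-pass
mask), the coefficient that estimator converges to can be written in closed
form from the lag-0 and lag-1 covariances of the observed process.  This
module computes those covariances spectrally:

1. cross-spectral density of the VAR(1) at the micro-step,
2. multiplication by the squared magnitude of the hemodynamic response,
3. spectral folding (aliasing) under decimation to the TR,
4. per-region variance normalization, additive white observation noise,
5. the binary band-pass mask,
6. inverse DFT back to lag-0/lag-1 covariance matrices.

Everything here is deterministic; the simulator's calibration inverts
``population_edge_betas`` numerically so that the generated cohorts carry the
path coefficients the estimator is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov


def spectral_radius(W: np.ndarray, influence_lag: int = 1) -> float:
    """Stability radius of ``z_t = diag(W) z_{t-1} + offdiag(W) z_{t-L} + e_t``.

    With ``influence_lag == 1`` this is the spectral radius of ``W`` itself;
    otherwise the radius of the companion matrix of the two-lag recursion
    (diagonal autoregression at the simulation step, directed influences at
    lag ``L`` steps).
    """
    W = np.asarray(W, dtype=float)
    L = int(influence_lag)
    if L == 1:
        return float(np.max(np.abs(np.linalg.eigvals(W))))
    r = W.shape[0]
    D = np.diag(np.diag(W))
    B = W - D
    comp = np.zeros((r * L, r * L))
    comp[:r, :r] = D
    comp[:r, r * (L - 1):] = B
    comp[r:, :-r] = np.eye(r * (L - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def stationary_cov(W: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Stationary covariance of ``z_t = W z_{t-1} + e_t``, ``e ~ N(0, Q)``.

    Solves the discrete Lyapunov equation ``S = W S W' + Q``.
    """
    W = np.asarray(W, dtype=float)
    if spectral_radius(W) >= 1.0:
        raise ValueError("VAR(1) is not stationary: spectral radius >= 1")
    return solve_discrete_lyapunov(W, np.asarray(Q, dtype=float))


@dataclass(frozen=True)
class ObservationChain:
    """Linear observation chain between neural VAR samples and analyzed data.

    Parameters
    ----------
    decimate :
        Integer decimation factor from the simulation micro-step to the TR.
        1 means the VAR is simulated directly at the TR.
    hrf_kernel :
        Hemodynamic impulse response sampled at the micro-step, or None for
        a purely neural (electrophysiology-like) observation.
    obs_noise_var :
        Variance of white observation noise added at the TR, on the scale of
        the unit-variance decimated signal.
    band :
        ``(low_hz, high_hz)`` ideal band-pass mask applied at the TR, or None.
    tr_s :
        Sampling interval of the analyzed series, seconds.
    n_freq :
        Number of TR-scale frequency bins used for the spectral integrals.
    """

    decimate: int = 1
    hrf_kernel: np.ndarray | None = None
    obs_noise_var: float = 0.0
    band: tuple[float, float] | None = None
    tr_s: float = 2.5
    n_freq: int = 1024


def _micro_lag_covariances(
    W: np.ndarray, Q: np.ndarray, L: int, max_lag: int
) -> np.ndarray:
    """Lag covariances ``C[d] = Cov(z_t, z_{t-d})`` of the two-lag VAR.

    The recursion ``z_t = D z_{t-1} + B z_{t-L} + e_t`` gives
    ``C(d) = D C(d-1) + B C(d-L)`` for d >= 1 (with ``C(-x) = C(x)'``);
    the first ``L`` lags come from the companion-form Lyapunov equation.
    """
    r = W.shape[0]
    D = np.diag(np.diag(W))
    B = W - D
    if L == 1:
        comp, Qc = W, Q
    else:
        comp = np.zeros((r * L, r * L))
        comp[:r, :r] = D
        comp[:r, r * (L - 1):] = B
        comp[r:, :-r] = np.eye(r * (L - 1))
        Qc = np.zeros((r * L, r * L))
        Qc[:r, :r] = Q
    Sc = solve_discrete_lyapunov(comp, Qc)
    C = np.empty((max_lag + 1, r, r))
    for d in range(min(L, max_lag + 1)):
        C[d] = Sc[:r, r * d: r * (d + 1)]
    dvec = np.diag(W)
    for d in range(L, max_lag + 1):
        back = C[d - L] if d >= L else C[L - d].T
        C[d] = dvec[:, None] * C[d - 1] + B @ back
    return C


def lagged_covariances(
    W: np.ndarray, Q: np.ndarray, chain: ObservationChain, influence_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Population lag-0 and lag-1 covariance of the observed TR-scale process.

    The generator is ``z_t = D z_{t-1} + B z_{t-L} + e_t`` with ``D`` the
    diagonal of ``W`` (autoregression at the simulation step), ``B`` its
    off-diagonal part (directed influences at lag ``L``) and ``L`` equal to
    ``influence_lag`` (default: the decimation factor, i.e. one TR).

    The computation is exact up to truncation of the (geometrically
    decaying) covariance sequence: micro-step lag covariances by companion
    Lyapunov plus recursion, hemodynamic convolution as a weighting with the
    kernel autocorrelation, decimation by sampling at multiples of the TR,
    then observation noise and the band mask applied on the TR-scale
    spectrum.

    Returns
    -------
    C0, C1 :
        ``C0[i, j] = Cov(y_i[t], y_j[t])`` and ``C1[i, j] = Cov(y_i[t],
        y_j[t-1])`` of the process after hemodynamic convolution, decimation,
        per-region standardization, observation noise and band masking.
    """
    W = np.asarray(W, dtype=float)
    Q = np.asarray(Q, dtype=float)
    m = int(chain.decimate)
    L = int(m if influence_lag is None else influence_lag)
    rad = spectral_radius(W, L)
    if rad >= 1.0:
        raise ValueError("VAR is not stationary: companion spectral radius >= 1")
    r = W.shape[0]

    # Truncation horizon: covariances decay like rad^lag at the micro-step.
    decay = max(rad, 0.05)
    K_tr = int(np.clip(np.log(1e-10) / (m * np.log(decay)), 8, 600))

    klen = 0 if chain.hrf_kernel is None else np.asarray(chain.hrf_kernel).size
    max_micro = K_tr * m + 2 * klen + 1
    C = _micro_lag_covariances(W, Q, L, max_micro)

    if chain.hrf_kernel is not None:
        h = np.asarray(chain.hrf_kernel, dtype=float)
        g = np.correlate(h, h, mode="full")  # lags -(klen-1) .. klen-1
        offs = np.arange(-(klen - 1), klen)
        # covariance for lags -(klen-1) .. K_tr*m + klen-1, negative lags
        # are transposes
        neg = C[1: klen].transpose(0, 2, 1)[::-1]  # lags -(klen-1) .. -1
        full = np.concatenate([neg, C[: K_tr * m + klen]])  # offset klen-1
        idx = np.arange(K_tr + 1)[:, None] * m + offs[None, :] + (klen - 1)
        R = np.einsum("g,tgij->tij", g, full[idx])
    else:
        R = np.stack([C[tau * m] for tau in range(K_tr + 1)])

    # standardize the decimated signal to unit variance per region
    d = 1.0 / np.sqrt(np.diag(R[0]))
    R = R * np.outer(d, d)[None, :, :]
    if chain.obs_noise_var > 0.0:
        R[0] = R[0] + chain.obs_noise_var * np.eye(r)

    # Band masking in the spectral domain is a lag-domain convolution with
    # the mask's inverse DFT: C_masked(u) = sum_tau w(u - tau) C(tau), so
    # C0 = sum_tau w(tau) R(tau) and C1 = sum_tau w(tau - 1) R(tau), using
    # R(-tau) = R(tau)'.
    w = _mask_weights(chain)
    if w is None:
        return R[0], R[1]

    def masked(shift: int) -> np.ndarray:
        K = min(K_tr, w.size - 1 - abs(shift))
        taus = np.arange(1, K + 1)
        out = w[abs(shift)] * R[0]
        out = out + np.einsum("k,kij->ij", w[np.abs(taus - shift)], R[1: K + 1])
        out = out + np.einsum("k,kji->ij", w[np.abs(-taus - shift)], R[1: K + 1])
        return out

    return masked(0), masked(1)


_MASK_WEIGHT_CACHE: dict[tuple, np.ndarray | None] = {}


def _mask_weights(chain: ObservationChain) -> np.ndarray | None:
    """Lag-domain weights of the band mask: ``w(tau) = IDFT(mask)(tau)``.

    Returns None when no band is configured (the mask is the identity).
    """
    if chain.band is None:
        return None
    key = (chain.band, chain.n_freq, chain.tr_s)
    if key not in _MASK_WEIGHT_CACHE:
        nf = int(chain.n_freq)
        lo, hi = chain.band
        f = np.minimum(np.arange(nf), nf - np.arange(nf)) / (nf * chain.tr_s)
        mask = ((f >= lo - 1e-12) & (f <= hi + 1e-12)).astype(float)
        _MASK_WEIGHT_CACHE[key] = np.fft.ifft(mask).real  # symmetric in tau
    return _MASK_WEIGHT_CACHE[key]


def beta_from_covariances(C0: np.ndarray, C1: np.ndarray, src: int, dst: int) -> float:
    """Population standardized lag-1 signed path coefficient src -> dst.

    The value the bivariate estimator converges to: the coefficient of the
    standardized ``src[t-1]`` in the regression of standardized ``dst[t]`` on
    ``[1, dst[t-1], src[t-1]]``.
    """
    sx = C0[src, src]
    sy = C0[dst, dst]
    r0 = C0[src, dst] / np.sqrt(sx * sy)
    a_y = C1[dst, dst] / sy
    r1 = C1[dst, src] / np.sqrt(sx * sy)
    return float((r1 - r0 * a_y) / (1.0 - r0**2))


def corr_from_covariances(C0: np.ndarray, a: int, b: int) -> float:
    """Population zero-lag Pearson correlation between regions a and b."""
    return float(C0[a, b] / np.sqrt(C0[a, a] * C0[b, b]))


def population_edge_betas(
    W: np.ndarray,
    Q: np.ndarray,
    edges: list[tuple[int, int]],
    chain: ObservationChain,
    corr_pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Population path coefficients for ``edges`` (and correlations for pairs).

    Returns the concatenation of the edge betas and, if ``corr_pairs`` is
    given, the zero-lag correlations of those pairs — the residual vector the
    network calibration drives to its targets.
    """
    C0, C1 = lagged_covariances(W, Q, chain)
    return _collect(C0, C1, edges, corr_pairs)


def _collect(C0, C1, edges, corr_pairs):
    out = [beta_from_covariances(C0, C1, s, d) for s, d in edges]
    if corr_pairs:
        out += [corr_from_covariances(C0, a, b) for a, b in corr_pairs]
    return np.asarray(out)
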