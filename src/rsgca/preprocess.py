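"""Time-series conditioning: volume discard, detrend, band-pass, nuisance regression.

The chain mirrors a standard resting-state pipeline at the point where data
become region x time matrices: discard initial volumes (longitudinal
magnetization equilibration), remove the per-column linear trend, apply an
ideal zero-phase frequency mask (0.01-0.08 Hz by default), and regress out
nuisance channels (motion analogues, global/physiological signals).  The
band-pass is realized as a binary DFT mask — zero phase, so it cannot bias
lag-1 directed coefficients — and confounds are filtered with the same mask
before regression so the nuisance projection stays exact in-band.

Seed extraction supports both parcel ("named-region") data and 4D NIfTI
volumes with a spherical seed defined in world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process."""


class CollinearityError(ValueError):
    """Raised when a confound matrix is rank deficient."""


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the conditioning chain.

    ``band_low_hz``/``band_high_hz`` bound the retained frequency band; the
    invariant ``0 <= low < high <= 1/(2 tr_s)`` is enforced at construction.
    """

    discard_initial: int = 5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    tr_s: float = 2.5
    nuisance_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 <= self.band_low_hz < self.band_high_hz <= nyquist + 1e-12):
            raise ValueError(
                f"band [{self.band_low_hz}, {self.band_high_hz}] Hz violates "
                f"0 <= low < high <= Nyquist ({nyquist:.4g} Hz)"
            )
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be non-negative")


@dataclass(frozen=True)
class SeedSpec:
    """A seed region: named parcel or sphere in world millimetres."""

    name: str
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 6.0
    mode: str = "named"  # {"named", "sphere"}

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.mode not in {"named", "sphere"}:
            raise ValueError("mode must be 'named' or 'sphere'")
        if self.mode == "sphere" and self.center_mm is None:
            raise ValueError("sphere mode requires center_mm")


def discard_initial(series: np.ndarray, n: int) -> np.ndarray:
    """Drop the first ``n`` timepoints (rows)."""
    series = np.asarray(series, dtype=float)
    if n >= series.shape[0]:
        raise DegenerateInputError(
            f"cannot discard {n} of {series.shape[0]} timepoints"
        )
    return series[n:].copy()


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from every column.

    Output columns have zero mean and zero linear trend.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    if t < 3:
        raise DegenerateInputError("detrend requires at least 3 timepoints")
    x = np.arange(t, dtype=float)
    x = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
    centered = series - series.mean(axis=0)
    return centered - np.outer(x, x @ centered)


def bandpass(series: np.ndarray, cfg: PreprocConfig) -> np.ndarray:
    """Zero-phase ideal band-pass: DFT bins outside the band are zeroed."""
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    freqs = np.fft.rfftfreq(t, d=cfg.tr_s)
    keep = (freqs >= cfg.band_low_hz - 1e-12) & (freqs <= cfg.band_high_hz + 1e-12)
    spec = np.fft.rfft(series, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=0)


def regress_nuisance(
    series: np.ndarray,
    confounds: np.ndarray,
    names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Residualize each column of ``series`` on ``[intercept | confounds]``.

    Raises
    ------
    CollinearityError
        If the confound matrix (with intercept) is rank deficient; the
        message names the offending columns.
    """
    series = np.asarray(series, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.shape[0]:
        raise DegenerateInputError(
            f"confounds have {confounds.shape[0]} timepoints, series has "
            f"{series.shape[0]}"
        )
    X = np.column_stack([np.ones(series.shape[0]), confounds])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _rank_deficient_columns(X, names)
        raise CollinearityError(f"confound matrix is rank deficient: {bad}")
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    return series - X @ beta


def _rank_deficient_columns(X: np.ndarray, names: tuple[str, ...] | None) -> str:
    r_diag = np.abs(np.diag(np.linalg.qr(X)[1]))
    tol = r_diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [i - 1 for i in np.nonzero(r_diag < tol)[0] if i > 0]  # skip intercept
    if names:
        return ", ".join(names[i] if i < len(names) else f"column {i}" for i in bad)
    return ", ".join(f"column {i}" for i in bad)


def preprocess_series(
    series: np.ndarray,
    cfg: PreprocConfig,
    confounds: np.ndarray | None = None,
    confound_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Full conditioning chain: discard -> detrend -> band-pass -> regression.

    Confounds are trimmed, detrended and band-passed with the same operators
    as the data before the final regression.
    """
    out = discard_initial(series, cfg.discard_initial)
    out = detrend_linear(out)
    out = bandpass(out, cfg)
    if confounds is not None and np.size(confounds):
        conf = discard_initial(np.atleast_2d(np.asarray(confounds, float)),
                               cfg.discard_initial)
        conf = bandpass(detrend_linear(conf), cfg)
        # drop confound columns emptied by the filter (e.g. pure linear drift)
        keep = conf.std(axis=0) > 1e-12
        if keep.any():
            kept_names = (
                tuple(n for n, k in zip(confound_names, keep) if k)
                if confound_names else None
            )
            out = regress_nuisance(out, conf[:, keep], kept_names)
    return out


class EmptySeedError(ValueError):
    """Raised when a seed sphere contains no voxels."""


def extract_seed(data, seed: SeedSpec, region_names: list[str] | None = None) -> np.ndarray:
    """Mean time series of a seed region.

    Parameters
    ----------
    data :
        Either a timepoints x regions matrix (named mode, with
        ``region_names``) or a ``nibabel`` spatial image with a 4D array
        (sphere mode); voxel centers are mapped to world millimetres through
        the image affine and averaged within ``radius_mm`` of ``center_mm``.
    """
    if seed.mode == "named":
        if region_names is None:
            raise ValueError("named-region extraction requires region_names")
        mat = np.asarray(data, dtype=float)
        try:
            col = region_names.index(seed.name)
        except ValueError as exc:
            raise KeyError(f"region {seed.name!r} not found") from exc
        return mat[:, col].copy()

    img = data
    vol = np.asanyarray(img.dataobj)
    if vol.ndim != 4:
        raise DegenerateInputError("sphere extraction requires a 4D image")
    affine = img.affine
    nx, ny, nz, _ = vol.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = vox @ affine.T
    d2 = ((world[:, :3] - np.asarray(seed.center_mm)) ** 2).sum(axis=1)
    inside = d2 <= seed.radius_mm**2
    if not inside.any():
        raise EmptySeedError(
            f"seed sphere at {seed.center_mm} mm (r={seed.radius_mm}) contains "
            "no voxel centers"
        )
    flat = vol.reshape(-1, vol.shape[3])
    return flat[inside].mean(axis=0)
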