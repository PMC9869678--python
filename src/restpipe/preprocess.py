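"""Post-realignment preprocessing chain.

Order enforced by the pipeline entry point: volume discard, nuisance
regression (24-parameter motion model plus WM/CSF series), band-pass
filtering.  Framewise displacement, motion exclusion, gray-matter mask
construction and Gaussian smoothing are stand-alone utilities; smoothing
order is metric-specific and handled by the metrics layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.ndimage import gaussian_filter

from .core import BoldSeries, MotionTrace, TissueMask

DEFAULT_HEAD_RADIUS_MM = 50.0
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm); first value is zero."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FD series must be 1D")
        if self.values[0] != 0:
            raise ValueError("FD at the first volume must be 0")
        if np.any(self.values < 0):
            raise ValueError("FD values must be nonnegative")

    @property
    def mean_fd(self) -> float:
        return float(self.values[1:].mean())


def discard_initial(bold: BoldSeries, n_discard: int = 10) -> BoldSeries:
    """Drop the first ``n_discard`` volumes."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= bold.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes"
        )
    return bold.evolve(bold.data[..., n_discard:], f"discard_initial({n_discard})")


def friston24(motion: MotionTrace) -> np.ndarray:
    """24-column motion design: [p(t), p(t-1), p(t)^2, p(t-1)^2].

    The lagged columns have zeros in their first row.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("motion trace must have at least 2 volumes")
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p**2, lag**2])


def regress_nuisance(bold: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Per-voxel OLS residuals against [intercept | regressors].

    Rank-deficient designs are reduced to an independent column subset
    (warning issued); residuals are orthogonal to every retained column.
    """
    X = np.column_stack([np.ones(bold.n_volumes), np.asarray(regressors, float)])
    if X.shape[0] != bold.n_volumes:
        raise ValueError("regressor rows must equal the number of volumes")
    if not np.all(np.isfinite(X)):
        raise ValueError("regressors contain non-finite values")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR keeps a maximal independent subset, intercept first
        _, _, piv = qr(X, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"rank-deficient nuisance design: dropping columns "
            f"{sorted(set(range(X.shape[1])) - set(keep))}",
            stacklevel=2,
        )
        X = X[:, keep]

    Y = bold.data.reshape(-1, bold.n_volumes).T  # (t, voxels)
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = (Y - X @ beta).T.reshape(bold.data.shape)
    return bold.evolve(resid, f"regress_nuisance(k={X.shape[1] - 1})")


def bandpass(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldSeries:
    """Rectangular frequency-domain band-pass after linear detrend."""
    nyquist = 0.5 / bold.tr
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must lie inside (0, {nyquist}) Hz"
        )
    T = bold.n_volumes
    Y = bold.data.reshape(-1, T)
    t = np.arange(T)
    # remove linear trend so edge discontinuities do not leak into the band
    A = np.column_stack([np.ones(T), t - t.mean()])
    Y = Y - np.linalg.lstsq(A, Y.T, rcond=None)[0].T @ A.T

    spec = np.fft.rfft(Y, axis=1)
    freqs = np.fft.rfftfreq(T, d=bold.tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=1).reshape(bold.data.shape)
    return bold.evolve(out, f"bandpass({low_hz},{high_hz})")


def framewise_displacement(
    motion: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> FDSeries:
    """Power-style FD: sum of absolute backward differences, rotations
    converted to arc length on a ``head_radius`` sphere."""
    if motion.n_volumes < 2:
        raise ValueError("motion trace must have at least 2 volumes")
    d_trans = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(np.deg2rad(motion.rotations_deg), axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + head_radius * d_rot])
    return FDSeries(fd)


def exclusion_check(
    motion: MotionTrace, max_trans: float = 2.0, max_rot: float = 2.0
) -> tuple[bool, str]:
    """Motion screen: fail when any axis exceeds the translation (mm) or
    rotation (degree) limit.  Returns (passed, reason)."""
    t_max = np.abs(motion.translations).max(axis=0)
    r_max = np.abs(motion.rotations_deg).max(axis=0)
    reasons = []
    for ax, name in enumerate("xyz"):
        if t_max[ax] > max_trans:
            reasons.append(f"translation {name}={t_max[ax]:.2f}mm > {max_trans}mm")
        if r_max[ax] > max_rot:
            reasons.append(f"rotation {name}={r_max[ax]:.2f}deg > {max_rot}deg")
    if reasons:
        return False, "; ".join(reasons)
    return True, "ok"


def binarize_gm(prob: np.ndarray, cutoff: float = 0.2) -> TissueMask:
    """Strict threshold of a probability map (prob > cutoff)."""
    prob = np.asarray(prob, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob > cutoff
    if not mask.any():
        raise ValueError(f"gray-matter mask empty at cutoff {cutoff}")
    return TissueMask(mask, source_cutoff=cutoff)


def gaussian_smooth(data, voxel_size, fwhm_mm: float = 6.0):
    """Separable spatial Gaussian smoothing of a 3D map or 4D series.

    sigma per axis = fwhm / (voxel_size * sqrt(8 ln 2)); fwhm 0 is identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if isinstance(data, BoldSeries):
        out = gaussian_smooth(data.data, voxel_size, fwhm_mm)
        return data.evolve(out, f"gaussian_smooth(fwhm={fwhm_mm})")
    arr = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return arr.copy()
    sigma = [fwhm_mm * FWHM_TO_SIGMA / float(v) for v in voxel_size]
    if arr.ndim == 4:
        sigma = sigma + [0.0]
    elif arr.ndim != 3:
        raise ValueError("expected a 3D map or 4D series")
    return gaussian_filter(arr, sigma=sigma, mode="constant", truncate=6.0)


def preprocess_bold(
    bold: BoldSeries,
    motion: MotionTrace,
    wmcsf: np.ndarray | None = None,
    n_discard: int = 0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> tuple[BoldSeries, BoldSeries, FDSeries]:
    """Canonical chain: discard -> nuisance regression -> band-pass.

    Returns (band-passed series, nuisance-regressed full-spectrum series,
    FD series).  The full-spectrum residual series is what fALFF consumes.
    """
    if n_discard:
        bold = discard_initial(bold, n_discard)
        motion = MotionTrace(motion.params[n_discard:])
        if wmcsf is not None:
            wmcsf = np.asarray(wmcsf)[n_discard:]
    regs = friston24(motion)
    if wmcsf is not None:
        regs = np.hstack([regs, np.asarray(wmcsf, float)])
    resid = regress_nuisance(bold, regs)
    banded = bandpass(resid, low_hz, high_hz)
    fd = framewise_displacement(motion)
    return banded, resid, fd
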