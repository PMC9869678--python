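"""Voxelwise local measures: fALFF, ReHo, degree centrality, VMHC, FCS.

Conventions:

* fALFF consumes the nuisance-regressed but NOT band-passed series (the
  ratio needs the full spectrum) and is computed on spatially smoothed
  data.
* ReHo, DC and FCS consume the band-passed, unsmoothed series; their
  standardized maps are smoothed afterwards.
* VMHC correlates each voxel with its mid-sagittal mirror on a
  symmetrized mask and is Fisher-z standardized.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .core import BoldSeries, LR_AXIS, MetricMap, TissueMask

FISHER_CLIP = 1.0 - 1e-7
_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
]


def _masked_series(bold: BoldSeries, mask: TissueMask) -> np.ndarray:
    return bold.data[mask.data]  # (n_voxels, t)


def _scatter(values: np.ndarray, mask: TissueMask, shape) -> np.ndarray:
    out = np.zeros(shape)
    out[mask.data] = values
    return out


def falff(
    bold: BoldSeries,
    mask: TissueMask,
    low_band: tuple[float, float] = (0.01, 0.08),
    full_band: tuple[float, float] = (0.0, 0.25),
) -> MetricMap:
    """Ratio of summed square-root power in the low band to the full band.

    The DC bin is excluded from both sums, so the result lies in [0, 1].
    """
    T = bold.n_volumes
    if T < 32:
        raise ValueError("need at least 32 time points for fALFF")
    series = _masked_series(bold, mask)
    amp = np.abs(np.fft.rfft(series, axis=1))
    freqs = np.fft.rfftfreq(T, d=bold.tr)
    eps = 1e-12
    low = (freqs >= low_band[0] - eps) & (freqs <= low_band[1] + eps) & (freqs > 0)
    full = (freqs > max(full_band[0], 0.0)) & (freqs <= full_band[1] + eps)
    num = amp[:, low].sum(axis=1)
    den = amp[:, full].sum(axis=1)
    zero = den == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero series: fALFF set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return MetricMap(_scatter(vals, mask, bold.spatial_shape), metric="fALFF")


def reho(bold: BoldSeries, mask: TissueMask) -> MetricMap:
    """Kendall concordance of each voxel with its 26 in-mask neighbors.

    w = 12 * sum_t (R_t - m(n+1)/2)^2 / (m^2 (n^3 - n)) where R_t is the
    cross-series rank sum at time t and m the number of series used (27
    interior, fewer at mask edges).  Constant series get w = 0.
    """
    data = bold.data
    T = bold.n_volumes
    valid = mask.data & (data.std(axis=3) > 0)
    n_const = int(mask.n_voxels - valid.sum())
    if n_const:
        warnings.warn(f"{n_const} constant series: ReHo set to 0", stacklevel=2)

    ranks = np.zeros_like(data)
    ranks[valid] = rankdata(data[valid], axis=1)

    shape = bold.spatial_shape
    rank_sum = np.zeros(shape + (T,))
    m = np.zeros(shape)
    for off in _NEIGHBOR_OFFSETS:
        src = tuple(
            slice(max(-o, 0), s - max(o, 0)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(o, 0), s - max(-o, 0)) for o, s in zip(off, shape)
        )
        rank_sum[dst] += ranks[src]
        m[dst] += valid[src]

    mean_rank_sum = m * (T + 1) / 2.0
    S = ((rank_sum - mean_rank_sum[..., None]) ** 2).sum(axis=3)
    denom = m**2 * (T**3 - T)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, 12.0 * S / np.where(denom > 0, denom, 1.0), 0.0)
    w = np.where(valid, w, 0.0)
    return MetricMap(np.clip(w, 0.0, 1.0) * mask.data, metric="ReHo")


def _standardized_rows(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that X @ X.T is the correlation matrix; flags zero-variance."""
    c = series - series.mean(axis=1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=1))
    ok = norm > 0
    c[ok] /= norm[ok, None]
    c[~ok] = 0.0
    return c, ok


def _pairwise_accumulate(series, r_threshold, weight_fn, block=2048):
    """Accumulate sum over j of weight_fn(r_ij) for r_ij > threshold, j != i."""
    Z, ok = _standardized_rows(series)
    n = Z.shape[0]
    acc = np.zeros(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        R = Z[start:stop] @ Z.T  # (b, n)
        np.clip(R, -1.0, 1.0, out=R)
        for local_i, i in enumerate(range(start, stop)):
            R[local_i, i] = 0.0  # exclude self
        W = np.where(R > r_threshold, weight_fn(R), 0.0)
        acc[start:stop] = W.sum(axis=1)
    acc[~ok] = 0.0
    return acc, ok


def degree_centrality(
    bold: BoldSeries,
    mask: TissueMask,
    r_threshold: float = 0.25,
    weighted: bool = True,
) -> MetricMap:
    """Weighted (sum of r) or binary degree over correlations r > threshold.

    Only positive suprathreshold correlations count; zero-variance voxels
    are excluded and get DC = 0.
    """
    if mask.n_voxels < 2:
        raise ValueError("need at least 2 mask voxels")
    series = _masked_series(bold, mask)
    fn = (lambda r: r) if weighted else (lambda r: np.ones_like(r))
    acc, _ = _pairwise_accumulate(series, r_threshold, fn)
    return MetricMap(_scatter(acc, mask, bold.spatial_shape), metric="DC")


def fcs(bold: BoldSeries, mask: TissueMask, r0: float = 0.2) -> MetricMap:
    """Mean Fisher-z of suprathreshold correlations.

    FC(i) = (1/(N-1)) * sum over j != i, r_ij > r0 of atanh(r_ij), with N
    the full mask voxel count (not the suprathreshold edge count).
    """
    if mask.n_voxels < 2:
        raise ValueError("need at least 2 mask voxels")
    series = _masked_series(bold, mask)
    fn = lambda r: np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    acc, _ = _pairwise_accumulate(series, r0, fn)
    vals = acc / (mask.n_voxels - 1)
    return MetricMap(_scatter(vals, mask, bold.spatial_shape), metric="FCS")


def symmetrize_mask(mask: TissueMask) -> TissueMask:
    """Keep a voxel only when its mid-sagittal mirror is also in the mask."""
    return TissueMask(
        mask.data & np.flip(mask.data, axis=LR_AXIS),
        source_cutoff=mask.source_cutoff,
    )


def vmhc(bold: BoldSeries, mask: TissueMask) -> MetricMap:
    """Correlation of each voxel with its inter-hemispheric mirror.

    Computed on the symmetrized mask; the raw map is mirror-symmetric by
    construction.  Use ``standardize_map(..., 'fisher_z')`` for zVMHC.
    """
    sym = symmetrize_mask(mask)
    data = bold.data
    mirrored = np.flip(data, axis=LR_AXIS)
    a = data[sym.data]
    b = mirrored[sym.data]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ac * bc).sum(axis=1) / np.where(denom > 0, denom, 1), 0.0)
    return MetricMap(
        _scatter(np.clip(r, -1.0, 1.0), sym, bold.spatial_shape), metric="VMHC"
    )


def standardize_map(
    metric_map: MetricMap, method: str, mask: TissueMask
) -> MetricMap:
    """Fisher-z (atanh, correlation-valued maps) or within-mask z-scoring."""
    vals = metric_map.data[mask.data]
    if method == "fisher_z":
        if np.any(np.abs(vals) >= 1.0):
            warnings.warn("values at |r| >= 1 clipped before atanh", stacklevel=2)
        out_vals = np.arctanh(np.clip(vals, -FISHER_CLIP, FISHER_CLIP))
    elif method == "zscore":
        sd = vals.std()
        if sd == 0:
            raise ValueError("zero variance within mask: cannot z-score")
        out_vals = (vals - vals.mean()) / sd
    else:
        raise ValueError("method must be 'fisher_z' or 'zscore'")
    out = np.zeros_like(metric_map.data)
    out[mask.data] = out_vals
    return MetricMap(
        out,
        metric=metric_map.metric,
        standardized=method,
        smoothed=metric_map.smoothed,
        processing_log=metric_map.processing_log + [f"standardize({method})"],
    )


#: default standardization per metric (correlation-valued maps use atanh)
DEFAULT_STANDARDIZATION = {
    "fALFF": "zscore",
    "ReHo": "zscore",
    "DC": "zscore",
    "VMHC": "fisher_z",
    "FCS": "zscore",
}


def compute_local_metrics(
    banded: BoldSeries,
    full_spectrum: BoldSeries,
    mask: TissueMask,
    voxel_size,
    fwhm_mm: float = 6.0,
    r_dc: float = 0.25,
    r0: float = 0.2,
) -> dict[str, MetricMap]:
    """All five standardized (and smoothed) local metric maps.

    fALFF is smoothed before computation; ReHo/DC/VMHC/FCS are computed
    unsmoothed and their standardized maps smoothed afterwards.
    """
    from .preprocess import gaussian_smooth

    smoothed_full = gaussian_smooth(full_spectrum, voxel_size, fwhm_mm)
    maps = {}
    m = falff(smoothed_full, mask)
    m.smoothed = True
    m.processing_log.append("smooth_before")
    maps["fALFF"] = standardize_map(m, "zscore", mask)

    for name, raw in (
        ("ReHo", reho(banded, mask)),
        ("DC", degree_centrality(banded, mask, r_threshold=r_dc)),
        ("VMHC", vmhc(banded, mask)),
        ("FCS", fcs(banded, mask, r0=r0)),
    ):
        z = standardize_map(raw, DEFAULT_STANDARDIZATION[name], mask)
        z.data = gaussian_smooth(z.data, voxel_size, fwhm_mm)
        z.smoothed = True
        z.processing_log.append("smooth_after")
        maps[name] = z
    return maps
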