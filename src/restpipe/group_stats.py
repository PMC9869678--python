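"""Voxelwise covariate-adjusted group statistics with GRF cluster-extent
correction, cluster-to-ROI feature extraction, and demographics tests.

Cluster inference follows the expected-Euler-characteristic route for
Gaussianized t-fields: residual smoothness is estimated from spatial
derivatives of standardized residuals, the expected number of clusters at
the voxel-forming threshold comes from the 3D EC density, and cluster-size
p-values use the exponential tail of the cluster-extent distribution
(Friston-style), corrected for the expected cluster count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn

from .core import TissueMask

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Voxelwise t map plus what GRF inference needs."""

    t: np.ndarray
    df: int
    mask: TissueMask
    residual_fwhm_mm: np.ndarray = None  # per-axis FWHM in mm
    resels: float = None
    design_columns: list[str] = field(default_factory=list)
    voxel_size: tuple = (3.0, 3.0, 3.0)
    affine: np.ndarray = None


@dataclass
class ClusterROI:
    """A suprathreshold connected component that survived correction."""

    label: int
    voxels: np.ndarray  # (k, 3) voxel indices
    size: int
    peak_xyz: tuple
    peak_t: float
    direction: str  # "patient>control" | "patient<control"
    p_corrected: float

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def voxelwise_glm_ttest(
    maps: np.ndarray,
    groups,
    covariates: pd.DataFrame | None,
    mask: TissueMask,
    voxel_size=(3.0, 3.0, 3.0),
    affine=None,
    return_residuals: bool = False,
):
    """Per-voxel OLS of metric values on [intercept, group, covariates].

    ``maps`` is (n_subjects, x, y, z); the t statistic is for the group
    indicator (patient=1), i.e. patient-minus-control after adjustment.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    g = np.asarray([1.0 if v in (1, "patient") else 0.0 for v in groups])
    if g.sum() < 3 or (n - g.sum()) < 3:
        raise ValueError("need at least 3 subjects per group")

    cols = ["intercept", "group"]
    X = [np.ones(n), g]
    if covariates is not None:
        for name in covariates.columns:
            v = np.asarray(covariates[name], dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"covariate {name!r} has non-finite values")
            X.append(v)
            cols.append(name)
    X = np.column_stack(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix; columns: {cols}")

    Y = maps[:, mask.data]  # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv_gg = np.linalg.inv(X.T @ X)[1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * xtx_inv_gg)
        tvals = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)

    t_map = np.zeros(mask.data.shape)
    t_map[mask.data] = tvals
    stat = StatMap(
        t=t_map,
        df=df,
        mask=mask,
        design_columns=cols,
        voxel_size=tuple(voxel_size),
        affine=affine,
    )
    if return_residuals:
        return stat, resid
    return stat


def estimate_smoothness(
    residuals: np.ndarray, mask: TissueMask, voxel_size=(3.0, 3.0, 3.0)
) -> tuple[np.ndarray, float]:
    """Per-axis residual FWHM (mm) and the RESEL count of the mask.

    Uses the correlation of neighboring standardized residuals:
    rho(1) = 1 - var(diff)/2 per axis, FWHM = sqrt(-2 ln 2 / ln rho)
    voxels (exact for a Gaussian autocorrelation), floored at one voxel.
    ``residuals`` is (n_images, V_mask) as returned by the GLM.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim != 2 or res.shape[0] < 2:
        raise ValueError("need at least 2 residual images (n_images, n_voxels)")
    shape = mask.data.shape
    if min(shape) < 2:
        raise ValueError("mask grid too small to estimate smoothness")

    # normalize residuals voxelwise so each voxel's residual vector has unit norm
    norm = np.sqrt((res**2).sum(axis=0))
    norm[norm == 0] = 1.0
    u = res / norm

    vols = np.zeros((res.shape[0],) + shape)
    vols[:, mask.data] = u

    fwhm_vox = np.empty(3)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, shape[ax] - 1)
        sl_hi[ax] = slice(1, shape[ax])
        pair = mask.data[tuple(sl_lo)] & mask.data[tuple(sl_hi)]
        if not pair.any():
            fwhm_vox[ax] = 1.0
            continue
        diff = (
            vols[(slice(None),) + tuple(sl_hi)] - vols[(slice(None),) + tuple(sl_lo)]
        )[:, pair]
        v = (diff**2).sum(axis=0).mean()  # E = 2(1 - rho) for unit-norm residuals
        rho = 1.0 - v / 2.0
        if rho <= 0 or rho >= 1:
            fwhm_vox[ax] = 1.0
        else:
            fwhm_vox[ax] = max(1.0, np.sqrt(-2.0 * np.log(2.0) / np.log(rho)))

    vs = np.asarray(voxel_size, dtype=float)
    fwhm_mm = fwhm_vox * vs
    resels = float(mask.n_voxels * np.prod(vs / fwhm_mm))
    return fwhm_mm, resels


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Gaussianize t values, numerically stable in both tails."""
    z = np.empty_like(t, dtype=float)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.cdf(t[~pos], df))
    return z


def _ec_density_3d(u: float) -> float:
    """3D Euler-characteristic density of a unit Gaussian field per resel."""
    return (
        (4.0 * np.log(2.0)) ** 1.5
        / (2.0 * np.pi) ** 2
        * (u**2 - 1.0)
        * np.exp(-(u**2) / 2.0)
    )


def grf_cluster_p(k_voxels: int, u: float, resels: float, n_mask_voxels: int) -> float:
    """FWE-corrected p for a cluster of ``k_voxels`` at threshold ``u``."""
    em = max(resels * _ec_density_3d(u), 1e-300)  # expected cluster count
    en = n_mask_voxels * stats.norm.sf(u)  # expected suprathreshold voxels
    if en <= 0:
        return 1.0
    beta = (gamma_fn(2.5) * em / en) ** (2.0 / 3.0)
    p_size = np.exp(-beta * k_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_size))


def grf_cluster_threshold(
    stat: StatMap,
    voxel_p: float = 0.001,
    cluster_p: float = 0.01,
    connectivity: int = 26,
) -> list[ClusterROI]:
    """Two-sided voxel threshold + GRF cluster-extent correction.

    Both signs are processed; surviving clusters are tagged with their
    direction.  Returns an empty list when nothing survives.
    """
    if stat.resels is None:
        raise ValueError("estimate smoothness before cluster thresholding")
    structure = _STRUCTURES[connectivity]
    z = np.zeros_like(stat.t)
    z[stat.mask.data] = _t_to_z(stat.t[stat.mask.data], stat.df)
    u = stats.norm.isf(voxel_p / 2.0)

    clusters: list[ClusterROI] = []
    next_label = 1
    for sign, direction in ((1, "patient>control"), (-1, "patient<control")):
        above = (sign * z > u) & stat.mask.data
        labels, n_comp = ndimage.label(above, structure=structure)
        for comp in range(1, n_comp + 1):
            idx = np.argwhere(labels == comp)
            k = len(idx)
            p = grf_cluster_p(k, u, stat.resels, stat.mask.n_voxels)
            if p >= cluster_p:
                continue
            tv = stat.t[tuple(idx.T)]
            peak_i = idx[np.argmax(sign * tv)]
            if stat.affine is not None:
                peak_xyz = tuple(
                    np.asarray(peak_i, float) @ stat.affine[:3, :3].T
                    + stat.affine[:3, 3]
                )
            else:
                peak_xyz = tuple(peak_i.astype(float))
            clusters.append(
                ClusterROI(
                    label=next_label,
                    voxels=idx,
                    size=k,
                    peak_xyz=peak_xyz,
                    peak_t=float(tv[np.argmax(sign * tv)]),
                    direction=direction,
                    p_corrected=p,
                )
            )
            next_label += 1
    clusters.sort(key=lambda c: -c.size)
    for i, c in enumerate(clusters):
        c.label = i + 1
    return clusters


def extract_features(
    stacks: dict[str, np.ndarray],
    clusters: dict[str, list[ClusterROI]],
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Subjects x ROI-mean feature table.

    ``stacks[metric]`` is (n_subjects, x, y, z); each cluster contributes a
    column named ``<metric>@<label>``.  Metadata columns (group, age, sex,
    mean_fd) are carried from ``subjects``.
    """
    out = subjects.copy().reset_index(drop=True)
    for metric, rois in clusters.items():
        if metric not in stacks:
            raise KeyError(f"no map stack for metric {metric!r}")
        if not rois:
            logger.info("metric %s has no surviving clusters; no columns", metric)
            continue
        stack = np.asarray(stacks[metric])
        for roi in rois:
            vox = tuple(roi.voxels.T)
            out[f"{metric}@{roi.label}"] = stack[(slice(None),) + vox].mean(axis=1)
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if "@" in c]


def pooled_two_sample_t(n1, mean1, sd1, n2, mean2, sd2) -> tuple[float, float]:
    """Classical pooled-variance two-sample t (group1 minus group2) and p."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)


def sex_chi_square(n_male: int, n_female: int) -> tuple[float, float]:
    """Goodness-of-fit of sex counts against equal proportions (df=1,
    no continuity correction)."""
    res = stats.chisquare([n_male, n_female])
    return float(res.statistic), float(res.pvalue)


def demographics_tests(table: pd.DataFrame) -> dict:
    """Between-group age t-test and within-group sex chi-square summary."""
    out = {}
    groups = table["group"].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    by = {g: table[table["group"] == g] for g in groups}
    for g, sub in by.items():
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    g1, g2 = ("control", "patient") if set(groups) == {"control", "patient"} else groups
    a1, a2 = by[g1]["age"], by[g2]["age"]
    t, p = pooled_two_sample_t(
        len(a1), a1.mean(), a1.std(ddof=1), len(a2), a2.mean(), a2.std(ddof=1)
    )
    out["age_t"] = t
    out["age_p"] = p
    for g, sub in by.items():
        n_m = int((sub["sex"] == "M").sum())
        n_f = int((sub["sex"] == "F").sum())
        chi2, p = sex_chi_square(n_m, n_f)
        out[f"sex_chi2_{g}"] = chi2
        out[f"sex_p_{g}"] = p
    return out
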