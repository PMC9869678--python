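"""Reproducible two-group synthetic BOLD cohorts with injectable effects.

Each subject's series is a sum of band-limited (0.01-0.08 Hz) oscillations
shared within parcels, a global low-frequency component, WM/CSF-like
nuisance series with smooth spatial loadings, motion-derived drift and
white Gaussian noise.  Effects modify the generative parameters of one
group inside a chosen region, giving every downstream metric a known
ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import BoldSeries, GridSpec, LR_AXIS, MotionTrace, mirror_index
from .network_fc import sphere_mask

EFFECT_TARGETS = (
    "falff_amplitude",
    "local_synchrony",
    "hub_degree",
    "homotopic_coupling",
    "seed_coupling",
)
DIRECTIONS = ("patient_up", "patient_down")


@dataclass(frozen=True)
class Sphere:
    """A spherical region given in world coordinates (mm)."""

    center_xyz: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth group effect injected into the generative model.

    ``region`` is either a boolean voxel mask matching the grid or a
    :class:`Sphere`.  ``partner`` (second region) is required for
    ``seed_coupling`` and ignored otherwise.
    """

    target: str
    region: object
    magnitude: float
    direction: str = "patient_up"
    partner: object = None

    def __post_init__(self):
        if self.target not in EFFECT_TARGETS:
            raise ValueError(f"unknown effect target {self.target!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")
        if self.target == "seed_coupling" and self.partner is None:
            raise ValueError("seed_coupling requires a partner region")

    def resolve_region(self, grid: GridSpec) -> np.ndarray:
        return _resolve_region(self.region, grid)

    def resolve_partner(self, grid: GridSpec) -> np.ndarray:
        return _resolve_region(self.partner, grid)


def _resolve_region(region, grid: GridSpec) -> np.ndarray:
    if isinstance(region, Sphere):
        mask = sphere_mask(grid, region.center_xyz, region.radius_mm)
    else:
        mask = np.asarray(region)
        if mask.shape != grid.shape:
            raise ValueError(
                f"effect region shape {mask.shape} does not match grid "
                f"{grid.shape} (region outside grid)"
            )
        mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("effect region is empty or outside the grid")
    return mask


@dataclass(frozen=True)
class NoiseModel:
    """Generative amplitudes, all in units of the white-noise SD."""

    sigma_noise: float = 1.0
    low_amp: float = 1.0          # voxel-specific band-limited oscillation
    parcel_amp: float = 0.7      # parcel-shared oscillation
    global_coupling: float = 0.3  # loading on the global low-frequency signal
    wmcsf_amp: float = 0.5
    drift_amp: float = 0.15
    motion_step_sd: float = 0.02  # random-walk step SD (mm / degrees)
    force_motion_violation: bool = False


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    bold: BoldSeries
    motion: MotionTrace
    gm_prob: np.ndarray
    nuisance_signals: np.ndarray = None  # (t, 2) known WM/CSF-like series

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError("group must be 'patient' or 'control'")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if np.any(self.gm_prob < 0) or np.any(self.gm_prob > 1):
            raise ValueError("gm_prob values must lie in [0, 1]")


def mirror_voxel(index, grid: GridSpec):
    """Mid-sagittal mirror of a voxel index (involution, bijection)."""
    return mirror_index(index, grid)


def band_limited_noise(rng, n_series: int, n_volumes: int, tr: float,
                       low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """Unit-SD rows of Gaussian noise band-limited to [low_hz, high_hz]."""
    white = rng.standard_normal((n_series, n_volumes))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[:, ~keep] = 0.0
    sig = np.fft.irfft(spec, n=n_volumes, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def gm_probability_map(grid: GridSpec) -> np.ndarray:
    """Smooth centred blob covering roughly 60% of the grid above p=0.2."""
    coords = grid.world_coordinates()
    half = np.array(
        [grid.voxel_size[i] * grid.shape[i] / 2.0 for i in range(3)]
    )
    d2 = ((coords / half) ** 2).sum(axis=-1)
    # scale chosen so ~60% of voxels exceed the 0.2 binarization cutoff
    return np.clip(np.exp(-d2 / (2 * 0.59**2)), 0.0, 1.0)


def _parcel_labels(grid: GridSpec) -> np.ndarray:
    """Deterministic 4-parcel partition (x-half x y-half blocks)."""
    nx, ny, _ = grid.shape
    i, j, _k = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
    return (i * 2 // nx) * 2 + (j * 2 // ny)


def _smooth_loading(grid: GridSpec, phase: float) -> np.ndarray:
    """Fixed smooth spatial loading map in [0.2, 1]."""
    coords = grid.world_coordinates()
    half = max(grid.voxel_size[i] * grid.shape[i] / 2.0 for i in range(3))
    wave = np.sin(coords[..., 0] / half * 2.2 + phase) + np.cos(
        coords[..., 1] / half * 1.7 + 0.5 * phase
    )
    return 0.2 + 0.8 * (wave - wave.min()) / (np.ptp(wave) + 1e-12)


def _simulate_motion(rng, n_volumes: int, noise: NoiseModel) -> np.ndarray:
    steps = rng.normal(0.0, noise.motion_step_sd, size=(n_volumes, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    if noise.force_motion_violation:
        params[n_volumes // 2 :, 0] += 3.0  # push x-translation past 2 mm
    return params


def _affected_group(direction: str) -> str:
    # "patient_down" boosts controls instead, keeping amplitudes nonnegative
    return "patient" if direction == "patient_up" else "control"


def iter_cohort(
    n_patients: int,
    n_controls: int,
    grid: GridSpec | None = None,
    effects: tuple[EffectSpec, ...] = (),
    noise_model: NoiseModel | None = None,
    rng_seed: int = 0,
):
    """Yield :class:`SubjectRecord` objects one at a time (low memory)."""
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    grid = grid or GridSpec()
    noise = noise_model or NoiseModel()
    effects = tuple(effects)

    regions = [e.resolve_region(grid).ravel() for e in effects]
    partners = [
        e.resolve_partner(grid).ravel() if e.target == "seed_coupling" else None
        for e in effects
    ]
    mirrors = [
        np.flip(e.resolve_region(grid), axis=LR_AXIS).ravel()
        if e.target == "homotopic_coupling"
        else None
        for e in effects
    ]

    parcels = _parcel_labels(grid).ravel()
    n_parcels = parcels.max() + 1
    gm = gm_probability_map(grid)
    w_wm = _smooth_loading(grid, 0.0).ravel()
    w_csf = _smooth_loading(grid, 2.1).ravel()
    w_drift = _smooth_loading(grid, 4.2).ravel()

    groups = ["patient"] * n_patients + ["control"] * n_controls
    children = np.random.SeedSequence(rng_seed).spawn(len(groups))
    T, V = grid.n_volumes, grid.n_voxels

    for idx, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        age = float(np.clip(rng.normal(43.0, 12.0), 18.0, 80.0))
        sex = "M" if rng.random() < 0.5 else "F"

        u = band_limited_noise(rng, V, T, grid.tr)
        s = band_limited_noise(rng, n_parcels, T, grid.tr)
        g = band_limited_noise(rng, 1, T, grid.tr)[0]
        wmcsf = gaussian_filter1d(rng.standard_normal((2, T)), sigma=3.0, axis=1)
        wmcsf /= wmcsf.std(axis=1, keepdims=True)
        motion = _simulate_motion(rng, T, noise)
        drift = np.cumsum(rng.normal(0.0, 1.0, T))
        drift = (drift - drift.mean()) / (drift.std() + 1e-12)

        a_low = np.full(V, noise.low_amp)
        extra = np.zeros((V, T))
        for eff, reg, par, mir in zip(effects, regions, partners, mirrors):
            e_sig = band_limited_noise(rng, 1, T, grid.tr)[0]
            if group != _affected_group(eff.direction):
                continue
            if eff.target == "falff_amplitude":
                a_low[reg] *= 1.0 + eff.magnitude
            elif eff.target == "local_synchrony":
                extra[reg] += eff.magnitude * e_sig
            elif eff.target == "hub_degree":
                extra[reg] += eff.magnitude * g
            elif eff.target == "homotopic_coupling":
                extra[reg] += eff.magnitude * e_sig
                extra[mir] += eff.magnitude * e_sig
            elif eff.target == "seed_coupling":
                extra[reg] += eff.magnitude * e_sig
                extra[par] += eff.magnitude * e_sig

        data = (
            a_low[:, None] * u
            + noise.parcel_amp * s[parcels]
            + noise.global_coupling * g
            + extra
            + noise.wmcsf_amp * (w_wm[:, None] * wmcsf[0] + w_csf[:, None] * wmcsf[1])
            + noise.drift_amp * w_drift[:, None] * drift
            + noise.sigma_noise * rng.standard_normal((V, T))
        )

        yield SubjectRecord(
            subject_id=f"sub-{idx:03d}",
            group=group,
            age=age,
            sex=sex,
            bold=BoldSeries(
                data.reshape(grid.shape + (T,)),
                tr=grid.tr,
                affine=grid.affine,
                processing_log=["simulate"],
            ),
            motion=MotionTrace(motion),
            gm_prob=gm,
            nuisance_signals=wmcsf.T,
        )


def generate_cohort(
    n_patients: int,
    n_controls: int,
    grid: GridSpec | None = None,
    effects: tuple[EffectSpec, ...] = (),
    noise_model: NoiseModel | None = None,
    rng_seed: int = 0,
) -> list[SubjectRecord]:
    """Materialize the whole cohort; identical seed gives identical bytes."""
    return list(
        iter_cohort(n_patients, n_controls, grid, effects, noise_model, rng_seed)
    )


def write_cohort(records, grid: GridSpec, out_dir) -> Path:
    """Write per-subject NIfTI + motion table, the GM map and a manifest CSV."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    gm_path = out / "gm_prob.nii.gz"
    first = True
    for rec in records:
        bold_path = out / f"{rec.subject_id}_bold.nii.gz"
        motion_path = out / f"{rec.subject_id}_motion.txt"
        nib.save(
            nib.Nifti1Image(rec.bold.data.astype(np.float32), rec.bold.affine),
            bold_path,
        )
        np.savetxt(motion_path, rec.motion.params, fmt="%.6f")
        if first:
            nib.save(nib.Nifti1Image(rec.gm_prob.astype(np.float32), grid.affine), gm_path)
            first = False
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": f"{rec.age:.2f}",
                "sex": rec.sex,
                "bold": bold_path.name,
                "motion": motion_path.name,
                "gm_prob": gm_path.name,
            }
        )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
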