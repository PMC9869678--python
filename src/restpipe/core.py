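"""Core containers shared by every pipeline stage.

The sampling grid, 4D time series, tissue masks and voxelwise metric maps
are plain dataclasses wrapping numpy arrays; every transformation returns a
new object and appends to an ordered processing log so the applied order of
steps can be asserted downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

#: axis index of the left-right (mirror) direction, by convention axis 0
LR_AXIS = 0


def default_affine(shape, voxel_size) -> np.ndarray:
    """Voxel->world map centred so world x=0 is the mid-sagittal plane."""
    a = np.eye(4)
    for i in range(3):
        a[i, i] = voxel_size[i]
        a[i, 3] = -voxel_size[i] * (shape[i] - 1) / 2.0
    return a


@dataclass(frozen=True)
class GridSpec:
    """Acquisition grid: spatial shape, voxel size (mm), affine, TR (s)."""

    shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 2.0
    n_volumes: int = 170
    affine: np.ndarray = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "voxel_size", vs)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {shape}")
        if shape[LR_AXIS] % 2 != 0:
            raise ValueError(
                f"left-right axis must have even length so every voxel has a "
                f"mirror; got {shape[LR_AXIS]}"
            )
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.n_volumes < 20:
            raise ValueError("need at least 20 volumes")
        if self.affine is None:
            object.__setattr__(self, "affine", default_affine(shape, vs))
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
                raise ValueError("affine must be an invertible 4x4 matrix")
            object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to (n,3) world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        flat = self.voxel_to_world(idx.reshape(-1, 3))
        return flat.reshape(self.shape + (3,))


def mirror_index(index, grid: GridSpec):
    """Reflect a voxel index across the grid's mid-sagittal plane.

    The reflection is an involution and, on an even-width axis, a bijection
    of the voxel set onto itself.
    """
    idx = tuple(int(i) for i in index)
    for ax, i in enumerate(idx):
        if not 0 <= i < grid.shape[ax]:
            raise ValueError(f"voxel index {idx} outside grid {grid.shape}")
    return (grid.shape[LR_AXIS] - 1 - idx[0],) + idx[1:]


@dataclass
class BoldSeries:
    """One subject's 4D BOLD array (x, y, z, t) with TR, affine and a log."""

    data: np.ndarray
    tr: float
    affine: np.ndarray
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def evolve(self, data: np.ndarray, step: str) -> "BoldSeries":
        """Return a new series with ``step`` appended to the log."""
        return BoldSeries(
            data=data,
            tr=self.tr,
            affine=self.affine,
            processing_log=self.processing_log + [step],
        )


@dataclass
class TissueMask:
    """Binary 3D mask plus the probability cutoff that produced it."""

    data: np.ndarray
    source_cutoff: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty — nothing to analyze")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (t, 6)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]


#: allowed standardization states of a metric map
STANDARDIZATIONS = ("raw", "fisher_z", "zscore")


@dataclass
class MetricMap:
    """A voxelwise scalar map tagged with its metric name and state."""

    data: np.ndarray
    metric: str
    standardized: str = "raw"
    smoothed: bool = False
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("metric map must be 3D")
        if self.standardized not in STANDARDIZATIONS:
            raise ValueError(f"standardized must be one of {STANDARDIZATIONS}")


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from one master seed and a stage name."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**32)
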