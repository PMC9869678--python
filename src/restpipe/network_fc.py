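"""Seed-based functional connectivity: the 12 canonical network seeds,
spherical ROI construction in world coordinates, and voxelwise seed maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import BoldSeries, GridSpec, MetricMap, TissueMask

FISHER_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """A named network seed: world-mm centre plus sphere radius."""

    network: str
    region: str
    xyz: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("seed radius must be positive")
        object.__setattr__(self, "xyz", tuple(float(v) for v in self.xyz))


def read_seed_table(path) -> list[SeedSpec]:
    """Load seeds from a CSV with columns network, region, x, y, z, radius."""
    df = pd.read_csv(path)
    required = {"network", "region", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"seed table missing columns: {sorted(missing)}")
    seeds = []
    for row in df.itertuples(index=False):
        radius = float(getattr(row, "radius", 6.0))
        seeds.append(
            SeedSpec(row.network, row.region, (row.x, row.y, row.z), radius)
        )
    return seeds


def builtin_seeds() -> list[SeedSpec]:
    """The 12 default network seeds (6 mm spheres, MNI mm coordinates)."""
    ref = resources.files("restpipe").joinpath("data/seeds.csv")
    with resources.as_file(ref) as path:
        return read_seed_table(path)


def sphere_mask(grid: GridSpec, center_xyz, radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose world-coordinate centre lies within
    ``radius_mm`` of ``center_xyz``."""
    coords = grid.world_coordinates()
    d2 = ((coords - np.asarray(center_xyz, dtype=float)) ** 2).sum(axis=-1)
    return d2 <= float(radius_mm) ** 2


def seed_mask(seed: SeedSpec, grid: GridSpec) -> TissueMask:
    m = sphere_mask(grid, seed.xyz, seed.radius)
    if not m.any():
        raise ValueError(
            f"seed {seed.network!r} ({seed.region!r}) at {seed.xyz} falls "
            f"outside the field of view"
        )
    return TissueMask(m)


def seed_fc_map(
    bold: BoldSeries,
    seed: SeedSpec,
    gm_mask: TissueMask,
    grid: GridSpec | None = None,
) -> MetricMap:
    """Fisher-z map of the correlation between the seed-mean series and
    every gray-matter voxel.

    The seed mean is computed over seed-sphere voxels intersected with the
    gray-matter mask.
    """
    if grid is None:
        grid = GridSpec(
            shape=bold.spatial_shape,
            tr=bold.tr,
            n_volumes=bold.n_volumes,
            affine=bold.affine,
        )
    sphere = seed_mask(seed, grid).data & gm_mask.data
    if not sphere.any():
        raise ValueError(
            f"seed {seed.network!r} does not overlap the gray-matter mask"
        )
    ref = bold.data[sphere].mean(axis=0)
    if ref.std() == 0:
        raise ValueError(f"seed {seed.network!r} mean series has zero variance")

    vox = bold.data[gm_mask.data]
    vox_c = vox - vox.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean()
    denom = np.sqrt((vox_c**2).sum(axis=1)) * np.sqrt((ref_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vox_c @ ref_c) / denom
    r = np.nan_to_num(r, nan=0.0)
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))

    out = np.zeros(bold.spatial_shape)
    out[gm_mask.data] = z
    return MetricMap(out, metric=f"seedFC:{seed.network}", standardized="fisher_z")


def seed_fc_all(bold, seeds, gm_mask, grid=None) -> dict[str, MetricMap]:
    """One Fisher-z map per seed; exactly len(seeds) maps."""
    return {s.network: seed_fc_map(bold, s, gm_mask, grid) for s in seeds}
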