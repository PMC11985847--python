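"""Contrast-specific seed masks: unions of fixed-radius spheres.

A seed is the union of closed balls of one radius around a contrast's
peak coordinates, rasterised on the analysis grid (a voxel belongs to a
sphere iff its *center* lies within the radius) and intersected with
the gray-matter mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrasts import ContrastRecord, Space
from .errors import EmptySeedError, EmptySphereError, GridMismatchError, InvalidArgumentError
from .grids import BrainGrid

__all__ = ["SeedMask", "sphere_mask", "build_contrast_seed"]


@dataclass(frozen=True)
class SeedMask:
    grid: BrainGrid
    mask: np.ndarray
    contrast_id: str
    radius_mm: float

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise GridMismatchError("seed mask shape does not match grid")
        if not mask.any():
            raise EmptySeedError(f"seed for contrast {self.contrast_id} is empty")
        if float(self.radius_mm) <= 0:
            raise InvalidArgumentError("radius_mm must be positive")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "radius_mm", float(self.radius_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def sphere_mask(center_mm, radius_mm: float, grid: BrainGrid) -> np.ndarray:
    """Boolean volume: voxels whose centers lie within ``radius_mm`` of
    ``center_mm`` (closed ball, Euclidean distance in world mm).

    Raises :class:`EmptySphereError` when no voxel center falls inside
    the ball (sphere entirely off-grid or radius below half a voxel at
    an unlucky offset).
    """
    if radius_mm <= 0:
        raise InvalidArgumentError(f"radius must be positive, got {radius_mm}")
    center = np.asarray(center_mm, dtype=float)

    # Candidate voxel box around the center, padded for rotated affines.
    inv = np.linalg.inv(grid.affine)
    c_vox = center @ inv[:3, :3].T + inv[:3, 3]
    # Smallest singular value of the voxel->world map bounds how many
    # voxels one mm can span in any direction.
    smin = np.linalg.svd(grid.affine[:3, :3], compute_uv=False).min()
    pad = int(np.ceil(radius_mm / smin)) + 1
    lo = np.maximum(np.floor(c_vox).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(c_vox).astype(int) + pad, np.array(grid.shape) - 1)

    out = np.zeros(grid.shape, dtype=bool)
    if np.any(lo > hi):
        raise EmptySphereError(center)
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    xyz = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    inside = np.sqrt(((xyz - center) ** 2).sum(axis=1)) <= radius_mm
    if not inside.any():
        raise EmptySphereError(center)
    sel = ijk[inside].astype(int)
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return out


def build_contrast_seed(
    rec: ContrastRecord,
    radius_mm: float,
    grid: BrainGrid,
    intersect_gm: bool = True,
) -> SeedMask:
    """Union of spheres around a contrast's peaks, gray-matter masked.

    All peaks must be in MNI space.  An empty union after masking
    raises :class:`EmptySeedError`; the caller should then exclude the
    contrast (mirroring the exclusion rule for out-of-mask coordinates).
    """
    mask = np.zeros(grid.shape, dtype=bool)
    for p in rec.peaks:
        if p.space is not Space.MNI:
            raise InvalidArgumentError(
                f"contrast {rec.contrast_id}: peak in {p.space.value} space; convert first"
            )
        try:
            mask |= sphere_mask(p.xyz, radius_mm, grid)
        except EmptySphereError:
            # A single off-grid peak does not doom the contrast; the
            # union may still be non-empty.
            continue
    if intersect_gm:
        mask &= grid.gm_mask
    if not mask.any():
        raise EmptySeedError(
            f"contrast {rec.contrast_id}: no seed voxel survives (radius {radius_mm} mm)"
        )
    return SeedMask(grid, mask, rec.contrast_id, radius_mm)
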