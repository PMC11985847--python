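"""Voxel grids, world coordinates and NIfTI-1 volume I/O.

World coordinates follow the NIfTI convention (RAS+, millimetres); the
affine maps voxel indices to world mm and is stored in the sform on
output.  World-to-voxel conversion rounds half away from zero, and the
same rule is used everywhere in the package so that integer peak
coordinates land on a reproducible voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InvalidArgumentError, OutOfGridError

__all__ = [
    "BrainGrid",
    "Volume",
    "LabelVolume",
    "make_grid",
    "mni_grid",
    "round_half_away",
    "save_volume",
    "load_volume",
    "save_label_volume",
    "load_label_volume",
]


def round_half_away(x):
    """Round to nearest integer, halves away from zero.

    ``numpy.round`` rounds halves to even; reported peak coordinates are
    integers in mm, so ties occur in practice and need a fixed rule.
    """
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class BrainGrid:
    """A 3D voxel grid with a world affine and a gray-matter mask.

    Parameters
    ----------
    shape
        Voxels per axis, three positive integers.
    affine
        4x4 matrix mapping homogeneous voxel indices to world mm (RAS+).
    gm_mask
        Boolean array of ``shape``; the analysis domain.  Defaults to
        all-true when omitted.
    """

    shape: tuple
    affine: np.ndarray
    gm_mask: np.ndarray = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise InvalidArgumentError(f"shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidArgumentError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise InvalidArgumentError("affine is not invertible")
        spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        if np.any(spacing <= 0):
            raise InvalidArgumentError("voxel spacing must be strictly positive")
        gm = self.gm_mask
        if gm is None:
            gm = np.ones(shape, dtype=bool)
        gm = np.asarray(gm, dtype=bool)
        if gm.shape != shape:
            raise InvalidArgumentError("gm_mask shape does not match grid shape")
        if not gm.any():
            raise InvalidArgumentError("gm_mask must contain at least one voxel")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "gm_mask", gm)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size along each world axis (mm)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def with_gm_mask(self, gm_mask: np.ndarray) -> "BrainGrid":
        return BrainGrid(self.shape, self.affine, gm_mask)

    def voxel_to_world(self, ijk) -> np.ndarray:
        """World coordinates (mm) of one or more voxel indices."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz[0] if xyz.shape[0] == 1 else xyz

    def world_to_voxel(self, xyz_mm, strict: bool = True):
        """Nearest voxel index for a world coordinate.

        Raises :class:`OutOfGridError` when the index falls outside the
        grid (unless ``strict=False``, in which case the raw index is
        returned for the caller to inspect).
        """
        xyz = np.asarray(xyz_mm, dtype=float)
        inv = np.linalg.inv(self.affine)
        ijk = round_half_away(xyz @ inv[:3, :3].T + inv[:3, 3])
        idx = np.atleast_2d(ijk)
        if strict:
            bad = (idx < 0).any(axis=1) | (idx >= np.array(self.shape)).any(axis=1)
            if bad.any():
                b = int(np.flatnonzero(bad)[0])
                raise OutOfGridError(np.atleast_2d(xyz)[b], idx[b], self.shape)
        return tuple(ijk) if ijk.ndim == 1 else ijk

    def contains_voxel(self, ijk) -> bool:
        ijk = np.asarray(ijk)
        return bool((ijk >= 0).all() and (ijk < np.array(self.shape)).all())

    def same_geometry(self, other: "BrainGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


def make_grid(shape, spacing_mm, origin_mm=(0.0, 0.0, 0.0), gm_mask=None) -> BrainGrid:
    """Axis-aligned grid: affine = diag(spacing) with translation origin.

    ``origin_mm`` is the world coordinate of the center of voxel (0,0,0).
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise InvalidArgumentError(f"spacing must be 3 positive reals, got {spacing_mm}")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    return BrainGrid(tuple(shape), affine, gm_mask)


def mni_grid(spacing_mm: float = 3.0) -> BrainGrid:
    """Isotropic grid covering the standard MNI bounding box.

    The box spans [-90, 90] x [-126, 90] x [-72, 108] mm, the extent of
    the usual SPM analysis templates; at 3 mm this gives a 61 x 73 x 61
    grid.  The gray-matter mask is all-true; real analyses replace it.
    """
    s = float(spacing_mm)
    if s <= 0:
        raise InvalidArgumentError("spacing must be positive")
    lo = np.array([-90.0, -126.0, -72.0])
    hi = np.array([90.0, 90.0, 108.0])
    shape = tuple(int(np.floor((hi - lo)[i] / s)) + 1 for i in range(3))
    return make_grid(shape, (s, s, s), tuple(lo))


@dataclass(frozen=True)
class Volume:
    """A scalar field on a :class:`BrainGrid`."""

    grid: BrainGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise InvalidArgumentError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        inside = values[self.grid.gm_mask]
        if not np.all(np.isfinite(inside)):
            raise InvalidArgumentError("non-finite values inside gm_mask")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LabelVolume:
    """Integer parcellation on a grid; 0 is background.

    ``names`` maps every nonzero label present in ``labels`` to a
    network name.
    """

    grid: BrainGrid
    labels: np.ndarray
    names: dict

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise InvalidArgumentError("labels must be integral")
            labels = np.round(labels).astype(int)
        if labels.shape != self.grid.shape:
            raise InvalidArgumentError("labels shape does not match grid shape")
        if labels.min() < 0:
            raise InvalidArgumentError("labels must be non-negative")
        names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(names)
        if missing:
            raise InvalidArgumentError(f"labels without names: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", names)

    @property
    def present_labels(self):
        return sorted(set(np.unique(self.labels).tolist()) - {0})


def _check_loaded_grid(img, expect_grid):
    if expect_grid is not None:
        if tuple(img.shape[:3]) != tuple(expect_grid.shape):
            raise FormatError(
                f"file shape {tuple(img.shape[:3])} does not match declared grid "
                f"{tuple(expect_grid.shape)}"
            )
        if not np.allclose(img.affine, expect_grid.affine, atol=1e-4):
            raise FormatError("file affine does not match declared grid affine")


def save_volume(vol: Volume, path) -> Path:
    """Write a volume as float32 NIfTI-1 with the affine in the sform."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
    img.header.set_sform(vol.grid.affine, code=2)
    img.to_filename(str(path))
    return path


def load_volume(path, grid: BrainGrid = None) -> Volume:
    """Read a NIfTI volume; verify shape/affine when ``grid`` is given."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    _check_loaded_grid(img, grid)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path} is not a 3D volume (ndim={data.ndim})")
    g = grid if grid is not None else BrainGrid(data.shape, img.affine)
    return Volume(g, data)


def save_label_volume(lv: LabelVolume, path) -> Path:
    """Write labels as int16 NIfTI plus a JSON sidecar with the name map."""
    path = Path(path)
    img = nib.Nifti1Image(lv.labels.astype(np.int16), lv.grid.affine)
    img.header.set_sform(lv.grid.affine, code=2)
    img.to_filename(str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({str(k): v for k, v in lv.names.items()}, indent=1))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_label_volume(path, grid: BrainGrid = None, names: dict = None) -> LabelVolume:
    """Read an integer parcellation; names come from the JSON sidecar
    unless supplied explicitly (generic names are synthesised as a last
    resort)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    _check_loaded_grid(img, grid)
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path} contains non-integer labels")
    labels = np.round(data).astype(int)
    if names is None:
        sidecar = _sidecar_path(Path(path))
        if sidecar.exists():
            names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        else:
            names = {int(l): f"network_{int(l)}" for l in np.unique(labels) if l != 0}
    g = grid if grid is not None else BrainGrid(labels.shape, img.affine)
    return LabelVolume(g, labels, names)
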