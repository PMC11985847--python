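"""Seed-based functional connectivity and group-level inference.

Per subject: correlate the mean seed time course with every gray-matter
voxel (Pearson r, then Fisher z = artanh r).  Per contrast: enter the
subject z-maps into a voxelwise one-sample t-test of positive
connectivity, control the false discovery rate with Benjamini-Hochberg,
and binarise the surviving positive-t voxels into the contrast's
network map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSeedError,
    GridMismatchError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .grids import BrainGrid
from .preprocess import SubjectTimeSeries
from .seeds import SeedMask

logger = logging.getLogger(__name__)

__all__ = [
    "FCMap",
    "GroupTMap",
    "BinaryNetworkMap",
    "seed_timecourse",
    "fisher_z",
    "fc_zmap",
    "group_tmap",
    "fdr_bh",
    "binarize_positive",
]

#: |r| is clipped here before artanh so seed voxels (r ~ 1 against the
#: seed mean) do not overflow to infinity.
FISHER_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FCMap:
    """Per-subject seed-to-whole-brain Fisher-z connectivity volume."""

    grid: BrainGrid
    z_values: np.ndarray
    subject_id: str = ""
    contrast_id: str = ""

    def __post_init__(self):
        z = np.asarray(self.z_values, dtype=float)
        if z.shape != self.grid.shape:
            raise GridMismatchError("z_values shape does not match grid")
        if not np.all(np.isfinite(z[self.grid.gm_mask])):
            raise InvalidArgumentError("non-finite z inside gm_mask")
        object.__setattr__(self, "z_values", z)


@dataclass(frozen=True)
class GroupTMap:
    """Voxelwise one-sample t statistics with one-sided upper-tail p."""

    grid: BrainGrid
    t: np.ndarray
    p: np.ndarray
    n_subjects: int

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InsufficientDataError("need at least 2 subjects")
        for name in ("t", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(f"{name} shape does not match grid")
            object.__setattr__(self, name, arr)
        if np.any((self.p < 0) | (self.p > 1)):
            raise InvalidArgumentError("p outside [0, 1]")

    @property
    def df(self) -> int:
        return self.n_subjects - 1


@dataclass(frozen=True)
class BinaryNetworkMap:
    """One contrast's thresholded, binarised connectivity network."""

    grid: BrainGrid
    mask: np.ndarray
    contrast_id: str = ""
    q_level: float = None
    radius_mm: float = None

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise GridMismatchError("mask shape does not match grid")
        if np.any(mask & ~self.grid.gm_mask):
            raise InvalidArgumentError("network mask extends outside gm_mask")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def seed_timecourse(ts: SubjectTimeSeries, seed: SeedMask) -> np.ndarray:
    """Unweighted mean series across the seed's voxels, length T."""
    if not ts.grid.same_geometry(seed.grid):
        raise GridMismatchError("time series and seed are on different grids")
    return ts.data[seed.mask].mean(axis=0)


def fisher_z(r):
    """Variance-stabilising Fisher transform z = artanh(r).

    Accepts scalars or arrays with |r| <= 1 (a hair beyond, from
    floating-point round-off, is tolerated); |r| at or beyond the clip
    ceiling is pulled to +-(1 - 1e-7) so the transform stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-9):
        raise InvalidArgumentError("correlation magnitude exceeds 1")
    clipped = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    n_clip = int(np.sum(np.abs(r) > FISHER_CLIP))
    if n_clip:
        logger.debug("fisher_z clipped %d value(s) at |r| = 1 - 1e-7", n_clip)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def fc_zmap(ts: SubjectTimeSeries, seed: SeedMask) -> FCMap:
    """Seed-to-whole-brain Fisher-z map for one subject.

    Correlations are computed only inside the gray-matter mask; voxels
    with zero temporal variance get z = 0 (their count is logged).  A
    constant seed time course cannot be correlated and raises
    :class:`DegenerateSeedError`.
    """
    course = seed_timecourse(ts, seed)
    sc = course - course.mean()
    s_norm = np.sqrt((sc**2).sum())
    if s_norm == 0:
        raise DegenerateSeedError(
            f"seed time course for contrast {seed.contrast_id} is constant"
        )
    gm = ts.grid.gm_mask
    V = ts.data[gm]  # (n_gm, T)
    Vc = V - V.mean(axis=1, keepdims=True)
    v_norm = np.sqrt((Vc**2).sum(axis=1))
    flat = np.zeros(v_norm.shape)
    ok = v_norm > 0
    n_zero = int((~ok).sum())
    if n_zero:
        logger.debug("fc_zmap: %d zero-variance voxel(s) set to z=0", n_zero)
    flat[ok] = (Vc[ok] @ sc) / (v_norm[ok] * s_norm)
    z = np.zeros(ts.grid.shape)
    z[gm] = fisher_z(flat)
    return FCMap(ts.grid, z, subject_id=ts.subject_id, contrast_id=seed.contrast_id)


def group_tmap(zmaps) -> GroupTMap:
    """Voxelwise one-sample t-test across subjects' z-maps.

    t = mean(z) / (sd(z)/sqrt(n)) with the sample standard deviation
    (ddof 1); p is the upper-tail Student-t probability with n-1
    degrees of freedom (one-sided, testing connectivity > 0).  At
    zero-variance voxels: t = +inf, p = 0 when the mean is positive;
    t = 0, p = 1 when the mean is zero; t = -inf, p = 1 when negative.
    """
    zmaps = list(zmaps)
    if len(zmaps) < 2:
        raise InsufficientDataError("group t-test needs at least 2 z-maps")
    grid = zmaps[0].grid
    for m in zmaps[1:]:
        if not grid.same_geometry(m.grid):
            raise GridMismatchError("z-maps are on different grids")
    Z = np.stack([m.z_values for m in zmaps])  # (n, ...)
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    t = np.zeros(mean.shape)
    # identical inputs can leave ~1e-17 round-off in sd; treat as degenerate
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    t[~ok & (mean > 0)] = np.inf
    t[~ok & (mean < 0)] = -np.inf
    df = n - 1
    p = np.ones(mean.shape)
    p[ok] = stats.t.sf(t[ok], df)
    p[~ok & (mean > 0)] = 0.0  # degenerate voxels: mean<=0 keeps p=1
    return GroupTMap(grid, t, p, n)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over a flat family of p-values.

    Rejects all p <= p_(k) where k = max{ i : p_(i) <= i*q/m } (1-based
    ranks).  Returns a boolean array aligned with the input; an empty
    rejection set is a valid outcome.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise InvalidArgumentError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise InvalidArgumentError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(sorted_p <= thresholds)
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    cutoff = sorted_p[passing[-1]]
    return p <= cutoff


def binarize_positive(
    tm: GroupTMap,
    rejected: np.ndarray,
    contrast_id: str = "",
    q_level: float = None,
    radius_mm: float = None,
) -> BinaryNetworkMap:
    """Binarised network: FDR-rejected AND t > 0 AND gray matter.

    Only positive connectivity is retained; significant negative-t
    voxels are discarded.
    """
    rejected = np.asarray(rejected, dtype=bool)
    if rejected.shape != tm.grid.shape:
        raise GridMismatchError("rejection mask shape does not match grid")
    mask = rejected & (tm.t > 0) & tm.grid.gm_mask
    if not mask.any():
        logger.info("binarize_positive: empty network for contrast %r", contrast_id)
    return BinaryNetworkMap(tm.grid, mask, contrast_id, q_level, radius_mm)
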