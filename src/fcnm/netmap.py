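"""Network probability maps and the dysfunctional-network threshold.

The per-contrast binary networks are overlaid: each voxel's probability
is the fraction of contrasts whose network contains it.  Thresholding
at 60% (inclusive) defines the dysfunctional network — the set of
voxels connected to at least 60% of the contrast seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import BinaryNetworkMap
from .errors import GridMismatchError, InvalidArgumentError
from .grids import BrainGrid

logger = logging.getLogger(__name__)

__all__ = ["ProbabilityMap", "probability_map", "threshold_probability", "dice_coefficient"]


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel fraction of contrasts whose network includes the voxel."""

    grid: BrainGrid
    prob: np.ndarray
    n_contrasts: int
    radius_mm: float = None

    def __post_init__(self):
        prob = np.asarray(self.prob, dtype=float)
        if prob.shape != self.grid.shape:
            raise GridMismatchError("prob shape does not match grid")
        if np.any((prob < 0) | (prob > 1)):
            raise InvalidArgumentError("probabilities outside [0, 1]")
        counts = prob * self.n_contrasts
        if not np.allclose(counts, np.round(counts), atol=1e-9):
            raise InvalidArgumentError("prob * n_contrasts is not integral")
        object.__setattr__(self, "prob", prob)


def probability_map(maps) -> ProbabilityMap:
    """Overlay binary networks: voxelwise fraction of maps containing
    each voxel.  One map per contrast; duplicate contrast ids are
    rejected so no contrast is double-counted."""
    maps = list(maps)
    if not maps:
        raise InvalidArgumentError("need at least one binary network map")
    ids = [m.contrast_id for m in maps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidArgumentError(f"duplicate contrast_id(s) in overlay: {dupes}")
    grid = maps[0].grid
    radii = {m.radius_mm for m in maps}
    for m in maps[1:]:
        if not grid.same_geometry(m.grid):
            raise GridMismatchError("binary maps are on different grids")
    count = np.zeros(grid.shape, dtype=int)
    for m in maps:
        count += m.mask
    radius = radii.pop() if len(radii) == 1 else None
    return ProbabilityMap(grid, count / len(maps), len(maps), radius)


def threshold_probability(
    pm: ProbabilityMap, thr: float = 0.60, inclusive: bool = True
) -> BinaryNetworkMap:
    """Dysfunctional network: voxels with probability >= thr.

    The comparison is inclusive by default so that, e.g., 15 of 25
    contrasts counts as exactly 60%; ``inclusive=False`` gives the
    strict "more than" reading.
    """
    if not (0.0 < thr <= 1.0):
        raise InvalidArgumentError("thr must lie in (0, 1]")
    mask = pm.prob >= thr if inclusive else pm.prob > thr
    mask = mask & pm.grid.gm_mask
    return BinaryNetworkMap(
        pm.grid, mask, contrast_id=f"probability_thr_{thr:g}", radius_mm=pm.radius_mm
    )


def dice_coefficient(a: BinaryNetworkMap, b: BinaryNetworkMap) -> float:
    """Dice overlap 2|a n b| / (|a| + |b|); 1.0 when both masks are
    empty (logged, since that usually signals an upstream problem)."""
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError("masks are on different grids")
    na, nb = a.mask.sum(), b.mask.sum()
    if na + nb == 0:
        logger.warning("dice of two empty masks defined as 1.0")
        return 1.0
    return float(2.0 * np.logical_and(a.mask, b.mask).sum() / (na + nb))
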