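"""Overlap of the dysfunctional network with canonical brain networks.

The canonical parcellation is the seven Yeo-style cortical networks
(visual, somatomotor, dorsal attention, ventral attention, limbic,
frontoparietal, default) plus one subcortical network (amygdala,
hippocampus, basal ganglia, thalamus grouping), supplied as a label
volume.  For each network the report gives the number of overlapping
voxels, the network's own voxel count, their ratio, and whether the
ratio reaches the 10% significance rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nilearn.image import resample_img

from .connectivity import BinaryNetworkMap
from .errors import GridMismatchError, InvalidArgumentError
from .grids import BrainGrid, LabelVolume

logger = logging.getLogger(__name__)

__all__ = ["OverlapReport", "resample_atlas", "overlap_report"]

#: A dysfunctional network is deemed significantly associated with a
#: canonical network when it covers at least this fraction of it.
SIGNIFICANCE_THRESHOLD = 0.10


@dataclass(frozen=True)
class OverlapReport:
    """Per-canonical-network overlap table.

    ``table`` columns: network, n_network, n_overlap, proportion,
    significant — one row per canonical network, ordered by label.
    """

    table: pd.DataFrame
    significance_threshold: float = SIGNIFICANCE_THRESHOLD

    def proportion(self, network: str) -> float:
        row = self.table[self.table["network"] == network]
        if row.empty:
            raise KeyError(network)
        return float(row["proportion"].iloc[0])

    @property
    def significant_networks(self):
        return list(self.table.loc[self.table["significant"], "network"])

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path

    def write_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "significance_threshold": self.significance_threshold,
            "networks": self.table.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def resample_atlas(atlas: LabelVolume, grid: BrainGrid) -> LabelVolume:
    """Nearest-neighbour resampling of a parcellation onto a grid.

    Labels are categorical, so only nearest-neighbour interpolation is
    sensible: the output label set is a subset of the input's, never
    larger.  Raises when the fields of view do not overlap at all.
    """
    if atlas.grid.same_geometry(grid):
        return LabelVolume(grid, atlas.labels.copy(), dict(atlas.names))
    src = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine)
    try:
        out = resample_img(
            src,
            target_affine=grid.affine,
            target_shape=grid.shape,
            interpolation="nearest",
            force_resample=True,
            copy_header=True,
        )
    except Exception as exc:  # nilearn's BoundingBoxError, among others
        raise GridMismatchError(f"cannot resample atlas onto grid: {exc}") from exc
    labels = np.asarray(out.dataobj).astype(int)
    if atlas.labels.any() and not labels.any():
        raise GridMismatchError("atlas and target grid fields of view do not overlap")
    return LabelVolume(grid, labels, dict(atlas.names))


def overlap_report(
    dys: BinaryNetworkMap,
    atlas: LabelVolume,
    significance_threshold: float = SIGNIFICANCE_THRESHOLD,
) -> OverlapReport:
    """Quantify the dysfunctional network's overlap with each canonical
    network.

    Both numerator and denominator are restricted to the analysis
    gray-matter mask so they live in the same domain.  A network with
    zero in-mask voxels is reported with proportion 0 and a warning.
    """
    if not dys.grid.same_geometry(atlas.grid):
        raise GridMismatchError("dysfunctional map and atlas are on different grids")
    if not atlas.names:
        raise InvalidArgumentError("atlas has no labelled networks")
    gm = dys.grid.gm_mask
    rows = []
    for label in sorted(atlas.names):
        name = atlas.names[label]
        net = (atlas.labels == label) & gm
        n_net = int(net.sum())
        n_ov = int((net & dys.mask).sum())
        if n_net == 0:
            logger.warning("canonical network %r has no voxels inside gm_mask", name)
            prop = 0.0
        else:
            prop = n_ov / n_net
        rows.append(
            {
                "network": name,
                "n_network": n_net,
                "n_overlap": n_ov,
                "proportion": prop,
                "significant": bool(prop >= significance_threshold),
            }
        )
    table = pd.DataFrame(rows, columns=["network", "n_network", "n_overlap", "proportion", "significant"])
    return OverlapReport(table, significance_threshold)


def polar_plot(report: OverlapReport, path) -> Path:
    """Polar summary of overlap proportions (presentation only).

    Significant networks (>= threshold) are drawn in red, others in
    blue.  Requires matplotlib, which is an optional dependency.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    n = len(t)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    colors = ["red" if s else "tab:blue" for s in t["significant"]]
    ax.bar(angles, t["proportion"], width=2 * np.pi / n * 0.9, color=colors, alpha=0.7)
    ax.set_xticks(angles)
    ax.set_xticklabels(t["network"], fontsize=7)
    ax.set_title("Overlap with canonical networks")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
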