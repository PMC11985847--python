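"""Synthetic cohorts, atlases and contrast tables for pipeline testing.

The generator emulates the statistical structure that seed-based
network mapping relies on: each of ``n_networks`` parcels shares one
latent AR(1) time course, every voxel observes that latent (scaled by
``signal_strength``) plus white Gaussian noise, and nuisance structure
(global/white-matter/CSF drifts, random-walk head motion) is layered on
top so the denoising stages have something real to remove.  Ground
truth records which network each synthetic contrast targets, enabling
parameter-recovery scoring of the full pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .atlas import OverlapReport
from .contrasts import ContrastRecord, ContrastSet, Modality, PeakCoordinate, Space
from .errors import InvalidArgumentError
from .grids import BrainGrid, LabelVolume, make_grid
from .preprocess import FD_HEAD_RADIUS_MM, SubjectTimeSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GroundTruthEntry",
    "make_synthetic_atlas",
    "simulate_subject",
    "sample_contrasts",
    "evaluate_recovery",
    "default_gt_spec",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic resting-state cohort.

    Defaults give the package's reference scenario: a small 3-mm grid
    holding 8 block parcels, 40 subjects of 150 frames at TR 0.72 s,
    latent amplitude/noise ratio 0.7, mild temporal autocorrelation.
    """

    shape: tuple = (18, 22, 18)
    spacing_mm: float = 3.0
    n_networks: int = 8
    n_subjects: int = 40
    n_timepoints: int = 150
    tr_s: float = 0.72
    signal_strength: float = 0.7  # latent amplitude beta
    noise_sd: float = 1.0  # voxelwise white-noise sigma
    ar_coefficient: float = 0.3  # AR(1) coefficient of the latents
    motion_sd: float = 0.01  # random-walk step sd, mm per frame
    tissue_amplitude: float = 0.1  # amplitude of global/WM/CSF nuisance
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_networks", "n_subjects", "n_timepoints"):
            if int(getattr(self, name)) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be positive")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise InvalidArgumentError("ar_coefficient must lie in [0, 1)")
        if self.tr_s <= 0 or self.spacing_mm <= 0:
            raise InvalidArgumentError("tr_s and spacing_mm must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruthEntry:
    contrast_id: str
    target_network: str
    peaks: tuple  # of (x, y, z) mm


@dataclass(frozen=True)
class GroundTruth:
    entries: tuple

    @property
    def target_networks(self):
        return sorted({e.target_network for e in self.entries})

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = [
            {"contrast_id": e.contrast_id, "target_network": e.target_network,
             "peaks": [list(p) for p in e.peaks]}
            for e in self.entries
        ]
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(tuple(
            GroundTruthEntry(d["contrast_id"], d["target_network"],
                             tuple(tuple(p) for p in d["peaks"]))
            for d in raw
        ))


def _factor_triple(n: int) -> tuple:
    """Most cube-like factorisation a*b*c = n (e.g. 8 -> 2*2*2)."""
    best, best_score = (n, 1, 1), float("inf")
    for a in range(1, n + 1):
        if n % a:
            continue
        m = n // a
        for b in range(1, m + 1):
            if m % b:
                continue
            c = m // b
            score = max(a, b, c) / min(a, b, c)
            if score < best_score:
                best, best_score = tuple(sorted((a, b, c), reverse=True)), score
    return best


def make_synthetic_atlas(cfg: SimulationConfig) -> LabelVolume:
    """Block parcellation: ``n_networks`` disjoint rectangular parcels of
    roughly equal size tiling the grid interior (a one-voxel background
    border remains so parcels never touch the grid edge).  The union of
    parcels is the gray-matter mask.  Labels are 1..n; label ``n`` is
    named ``subcortical`` when eight or more networks are requested,
    matching the 7-cortical-plus-subcortical convention.
    """
    grid0 = make_grid(cfg.shape, (cfg.spacing_mm,) * 3)
    interior = [s - 2 for s in cfg.shape]
    if any(i < 1 for i in interior):
        raise InvalidArgumentError(f"grid {cfg.shape} too small for any parcel")
    # Assign the largest factor to the largest interior axis.
    factors = _factor_triple(int(cfg.n_networks))
    axis_order = np.argsort(interior)[::-1]
    per_axis = [1, 1, 1]
    for f, ax in zip(factors, axis_order):
        per_axis[ax] = f
    if any(per_axis[a] > interior[a] for a in range(3)):
        raise InvalidArgumentError(
            f"grid {cfg.shape} too small for {cfg.n_networks} parcels"
        )
    edges = [
        np.array_split(np.arange(1, cfg.shape[a] - 1), per_axis[a]) for a in range(3)
    ]
    labels = np.zeros(cfg.shape, dtype=int)
    label = 0
    for chunk_i in edges[0]:
        for chunk_j in edges[1]:
            for chunk_k in edges[2]:
                label += 1
                labels[np.ix_(chunk_i, chunk_j, chunk_k)] = label
    names = {k: f"network_{k}" for k in range(1, cfg.n_networks + 1)}
    if cfg.n_networks >= 8:
        names[cfg.n_networks] = "subcortical"
    grid = grid0.with_gm_mask(labels > 0)
    return LabelVolume(grid, labels, names)


def _ar1(rng: np.random.Generator, phi: float, n_series: int, T: int) -> np.ndarray:
    """Stationary AR(1) series with unit innovation variance, (n, T)."""
    out = np.empty((n_series, T))
    scale0 = 1.0 / np.sqrt(1.0 - phi**2) if phi else 1.0
    out[:, 0] = rng.standard_normal(n_series) * scale0
    innov = rng.standard_normal((n_series, T - 1))
    for t in range(1, T):
        out[:, t] = phi * out[:, t - 1] + innov[:, t - 1]
    return out


def simulate_subject(
    atlas: LabelVolume, cfg: SimulationConfig, subject_index: int
) -> SubjectTimeSeries:
    """One subject's 4D series on the atlas grid.

    Voxel v in network k observes ``beta * L_k(t) + nuisance(t) +
    eps_v(t)`` where L_k is the network's latent AR(1) course, the
    nuisance term sums three small-amplitude AR(1) tissue drifts shared
    by every voxel, and eps is white N(0, noise_sd^2).  Motion traces
    are Gaussian random walks (rotation steps scaled by the 50-mm head
    radius so their displacement contribution matches translations).
    Fully deterministic given ``(cfg.rng_seed, subject_index)``.
    """
    rng = np.random.default_rng([int(cfg.rng_seed), int(subject_index)])
    T = cfg.n_timepoints
    grid = atlas.grid
    latents = _ar1(rng, cfg.ar_coefficient, cfg.n_networks, T)
    tissue = _ar1(rng, cfg.ar_coefficient, 3, T)
    nuisance = cfg.tissue_amplitude * tissue.sum(axis=0)

    data = np.zeros(grid.shape + (T,))
    for k in range(1, cfg.n_networks + 1):
        sel = atlas.labels == k
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        noise = rng.standard_normal((n_vox, T)) * cfg.noise_sd
        data[sel] = cfg.signal_strength * latents[k - 1] + nuisance + noise

    steps = rng.standard_normal((T, 6))
    steps[:, :3] *= cfg.motion_sd
    steps[:, 3:] *= cfg.motion_sd / FD_HEAD_RADIUS_MM
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)

    tissue_signals = {
        "global": cfg.tissue_amplitude * tissue[0],
        "white_matter": cfg.tissue_amplitude * tissue[1],
        "csf": cfg.tissue_amplitude * tissue[2],
    }
    return SubjectTimeSeries(
        grid,
        data,
        cfg.tr_s,
        motion=motion,
        tissue_signals=tissue_signals,
        subject_id=f"sub-{subject_index:03d}",
    )


def default_gt_spec(target: str = "network_1", n_contrasts: int = 10, n_peaks: int = 3):
    """Reference recovery scenario: ``n_contrasts`` contrasts of
    ``n_peaks`` peaks, all targeting one network."""
    return [(target, n_peaks)] * n_contrasts


_MODALITY_CYCLE = (Modality.RS_FMRI, Modality.TASK_FMRI, Modality.VBM)


def sample_contrasts(
    atlas: LabelVolume,
    gt_spec,
    jitter_mm: float = 0.0,
    rng_seed: int = 0,
):
    """Draw synthetic contrasts whose peaks lie inside target networks.

    ``gt_spec`` is a list of ``(target_network_name, n_peaks)``; each
    entry becomes one contrast whose peaks are drawn uniformly (without
    replacement) from the network's voxel centers.  Optional jitter
    perturbs each peak uniformly in [-jitter_mm, +jitter_mm] per axis
    but is discarded when it would move the peak's voxel outside the
    network, so the ground-truth invariant always holds.  Returns
    ``(ContrastSet, GroundTruth)``.
    """
    rng = np.random.default_rng(int(rng_seed))
    name_to_label = {v: k for k, v in atlas.names.items()}
    records, entries = [], []
    for i, (target, n_peaks) in enumerate(gt_spec, start=1):
        if target not in name_to_label:
            raise InvalidArgumentError(f"unknown target network {target!r}")
        label = name_to_label[target]
        voxels = np.argwhere(atlas.labels == label)
        if len(voxels) == 0:
            raise InvalidArgumentError(f"target network {target!r} is empty")
        if n_peaks > len(voxels):
            raise InvalidArgumentError(
                f"{n_peaks} peaks requested but {target!r} has {len(voxels)} voxels"
            )
        chosen = voxels[rng.choice(len(voxels), size=n_peaks, replace=False)]
        peaks = []
        for ijk in chosen:
            xyz = atlas.grid.voxel_to_world(ijk)
            if jitter_mm > 0:
                for _ in range(10):
                    cand = xyz + rng.uniform(-jitter_mm, jitter_mm, size=3)
                    cand_ijk = atlas.grid.world_to_voxel(cand, strict=False)
                    if (
                        atlas.grid.contains_voxel(cand_ijk)
                        and atlas.labels[tuple(int(v) for v in cand_ijk)] == label
                    ):
                        xyz = cand
                        break
            peaks.append(PeakCoordinate(xyz[0], xyz[1], xyz[2], Space.MNI))
        cid = f"syn{i:02d}"
        records.append(
            ContrastRecord(
                study_id=f"synstudy{i:02d}",
                contrast_id=cid,
                modality=_MODALITY_CYCLE[(i - 1) % len(_MODALITY_CYCLE)],
                peaks=tuple(peaks),
                n_patients=15,
                n_controls=15,
            )
        )
        entries.append(
            GroundTruthEntry(cid, target, tuple((p.x, p.y, p.z) for p in peaks))
        )
    cs = ContrastSet(tuple(records), provenance=f"synthetic(seed={rng_seed})")
    return cs, GroundTruth(tuple(entries))


@dataclass(frozen=True)
class RecoveryResult:
    """Pass/fail scoring of an overlap report against ground truth."""

    target_network: str
    target_proportion: float
    max_nontarget_proportion: float
    max_nontarget_network: str
    passed: bool
    target_min: float
    nontarget_max: float


def evaluate_recovery(
    report: OverlapReport,
    gt: GroundTruth,
    target_min: float = 0.5,
    nontarget_max: float = 0.10,
) -> RecoveryResult:
    """Score recovery of a single-target scenario.

    Passes when the target network's overlap proportion reaches
    ``target_min`` and every other network stays below
    ``nontarget_max`` — the one-dominant-network pattern the method is
    supposed to produce.
    """
    targets = gt.target_networks
    if len(targets) != 1:
        raise InvalidArgumentError(
            f"recovery scoring expects one target network, got {targets}"
        )
    target = targets[0]
    names = list(report.table["network"])
    if target not in names:
        raise InvalidArgumentError(f"target network {target!r} absent from report")
    target_prop = report.proportion(target)
    others = report.table[report.table["network"] != target]
    if others.empty:
        max_nt, max_nt_name = 0.0, ""
    else:
        idx = others["proportion"].idxmax()
        max_nt = float(others.loc[idx, "proportion"])
        max_nt_name = str(others.loc[idx, "network"])
    passed = target_prop >= target_min and max_nt < nontarget_max
    return RecoveryResult(
        target, float(target_prop), max_nt, max_nt_name, bool(passed),
        target_min, nontarget_max,
    )
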