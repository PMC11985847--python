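"""End-to-end orchestration: ingest -> seeds -> FC -> group -> overlap.

The pipeline runs per seed radius: build each contrast's seed, stream
the cohort once computing every subject-by-seed Fisher-z map, run the
voxelwise one-sample t-test with BH-FDR per contrast, binarise the
positive surviving voxels, overlay the contrast networks into a
probability map, threshold it into the dysfunctional network, and
quantify overlap with the canonical parcellation.  All randomness lives
in the synthetic generator's seeds, so a given configuration is fully
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .atlas import OverlapReport, overlap_report, resample_atlas
from .connectivity import (
    BinaryNetworkMap,
    FCMap,
    binarize_positive,
    fc_zmap,
    fdr_bh,
    group_tmap,
)
from .contrasts import (
    ContrastSet,
    apply_gm_filter,
    convert_set_to_mni,
    parse_contrast_table,
    summarize_contrast_set,
    write_contrast_table,
)
from .errors import FCNMError, InvalidArgumentError
from .grids import (
    BrainGrid,
    LabelVolume,
    Volume,
    load_label_volume,
    load_volume,
    save_label_volume,
    save_volume,
)
from .netmap import ProbabilityMap, dice_coefficient, probability_map, threshold_probability
from .preprocess import (
    PreprocessConfig,
    SubjectTimeSeries,
    load_motion_parameters,
    preprocess_subject,
)
from .seeds import build_contrast_seed
from .simulate import (
    GroundTruth,
    SimulationConfig,
    default_gt_spec,
    evaluate_recovery,
    make_synthetic_atlas,
    sample_contrasts,
    simulate_subject,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RadiusResult",
    "AnalysisResult",
    "analyze_cohort",
    "run_pipeline",
    "write_synthetic_dataset",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; loadable from YAML.

    Either the file inputs (``contrast_table``, ``subjects``,
    ``atlas_path``) or the ``synthetic`` block must be provided.
    ``subjects`` is a list of ``[bold_path, motion_path]`` pairs
    (motion may be null).
    """

    output_dir: str = "fcnm_out"
    contrast_table: str = None
    subjects: tuple = None
    atlas_path: str = None
    gm_mask_path: str = None
    synthetic: SimulationConfig = None
    gt_spec: tuple = None
    jitter_mm: float = 0.0
    radii: tuple = (4.0,)
    q: float = 0.05
    prob_threshold: float = 0.60
    inclusive_threshold: bool = True
    one_sided: bool = True
    significance_threshold: float = 0.10
    per_modality: bool = True
    intersect_gm: bool = True
    tal_variant: str = "spm"
    preprocess: PreprocessConfig = None
    write_volumes: bool = True

    def __post_init__(self):
        if any(float(r) <= 0 for r in self.radii):
            raise InvalidArgumentError("radii must be positive")
        for name in ("q", "prob_threshold", "significance_threshold"):
            v = float(getattr(self, name))
            if not (0.0 < v <= 1.0):
                raise InvalidArgumentError(f"{name} must lie in (0, 1]")
        if self.synthetic is None and self.contrast_table is None:
            raise InvalidArgumentError("need either synthetic block or contrast_table")
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SimulationConfig(**raw["synthetic"])
        if "preprocess" in raw and raw["preprocess"] is not None:
            raw["preprocess"] = PreprocessConfig(**{
                k: tuple(v) if k == "band" and v is not None else v
                for k, v in raw["preprocess"].items()
            })
        for key in ("subjects", "gt_spec", "radii"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, (SimulationConfig,)):
                return v.to_dict()
            if isinstance(v, PreprocessConfig):
                return {**v.__dict__, "band": list(v.band) if v.band else None}
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RadiusResult:
    """Outputs of one seed radius."""

    radius_mm: float
    binary_maps: dict  # contrast_id -> BinaryNetworkMap
    prob_map: ProbabilityMap
    dysfunctional: BinaryNetworkMap
    per_modality_prob: dict = field(default_factory=dict)
    per_modality_dys: dict = field(default_factory=dict)
    overlap: OverlapReport = None
    n_rejected: dict = field(default_factory=dict)  # contrast_id -> voxel count


@dataclass
class AnalysisResult:
    grid: BrainGrid
    contrasts: ContrastSet
    n_subjects: int
    per_radius: dict  # radius -> RadiusResult
    dice: dict = field(default_factory=dict)  # (r1, r2) -> float
    warnings: list = field(default_factory=list)


def _contrast_network(zmaps, grid, q, one_sided, contrast_id, radius_mm):
    """t-test + FDR (family = gray-matter voxels) + positive binarise."""
    tm = group_tmap(zmaps)
    gm = grid.gm_mask
    if one_sided:
        p_family = tm.p[gm]
    else:
        from scipy import stats

        t_gm = tm.t[gm]
        p_family = np.ones(t_gm.shape)
        finite = np.isfinite(t_gm)
        p_family[finite] = 2.0 * stats.t.sf(np.abs(t_gm[finite]), tm.df)
        p_family[np.isinf(t_gm)] = 0.0
    rej_flat = fdr_bh(p_family, q)
    rejected = np.zeros(grid.shape, dtype=bool)
    rejected[gm] = rej_flat
    bn = binarize_positive(tm, rejected, contrast_id=contrast_id, q_level=q, radius_mm=radius_mm)
    return bn, tm


def analyze_cohort(
    contrasts: ContrastSet,
    subjects,
    grid: BrainGrid,
    *,
    radii=(4.0,),
    q: float = 0.05,
    prob_threshold: float = 0.60,
    inclusive_threshold: bool = True,
    one_sided: bool = True,
    preprocess_cfg: PreprocessConfig = None,
    atlas: LabelVolume = None,
    significance_threshold: float = 0.10,
    per_modality: bool = True,
    intersect_gm: bool = True,
) -> AnalysisResult:
    """Run the network-mapping core on an in-memory (or streamed) cohort.

    ``subjects`` is any iterable of :class:`SubjectTimeSeries`; it is
    consumed once.  ``preprocess_cfg=None`` means the data are used as
    given (already denoised).  When ``atlas`` is provided an overlap
    report is attached per radius.
    """
    warnings: list = []
    seeds = {}
    for r in radii:
        for rec in contrasts:
            seeds[(r, rec.contrast_id)] = build_contrast_seed(
                rec, r, grid, intersect_gm=intersect_gm
            )

    zmaps = {key: [] for key in seeds}
    n_subjects = 0
    for ts in subjects:
        if preprocess_cfg is not None:
            ts = preprocess_subject(ts, preprocess_cfg)
        if not ts.grid.same_geometry(grid):
            raise InvalidArgumentError(
                f"subject {ts.subject_id!r} is not on the analysis grid"
            )
        for key, seed in seeds.items():
            zmaps[key].append(fc_zmap(ts, seed))
        n_subjects += 1

    per_radius = {}
    for r in radii:
        binary, n_rej = {}, {}
        for rec in contrasts:
            bn, _ = _contrast_network(
                zmaps[(r, rec.contrast_id)], grid, q, one_sided, rec.contrast_id, r
            )
            binary[rec.contrast_id] = bn
            n_rej[rec.contrast_id] = bn.n_voxels
            if bn.n_voxels == 0:
                warnings.append(f"radius {r}: contrast {rec.contrast_id} network is empty")
        pm = probability_map(list(binary.values()))
        dys = threshold_probability(pm, prob_threshold, inclusive=inclusive_threshold)
        res = RadiusResult(r, binary, pm, dys, n_rejected=n_rej)

        if per_modality:
            by_mod = {}
            for rec in contrasts:
                by_mod.setdefault(rec.modality.value, []).append(binary[rec.contrast_id])
            for mod, maps in by_mod.items():
                if len(maps) >= 2:
                    mp = probability_map(maps)
                    res.per_modality_prob[mod] = mp
                    res.per_modality_dys[mod] = threshold_probability(
                        mp, prob_threshold, inclusive=inclusive_threshold
                    )
        if atlas is not None:
            atlas_on_grid = resample_atlas(atlas, grid)
            res.overlap = overlap_report(dys, atlas_on_grid, significance_threshold)
        per_radius[r] = res

    dice = {}
    rs = sorted(radii)
    for i, r1 in enumerate(rs):
        for r2 in rs[i + 1 :]:
            dice[(r1, r2)] = dice_coefficient(
                per_radius[r1].dysfunctional, per_radius[r2].dysfunctional
            )
    return AnalysisResult(grid, contrasts, n_subjects, per_radius, dice, warnings)


def _array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_synthetic_dataset(
    cfg: SimulationConfig, outdir, gt_spec=None, jitter_mm: float = 0.0
) -> dict:
    """Materialise a synthetic dataset on disk in the pipeline's input
    formats: atlas.nii.gz (+ names sidecar), one BOLD NIfTI and motion
    text file per subject, contrasts.tsv, ground_truth.json and a
    config.yaml snapshot.  Returns a manifest of the written paths."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = make_synthetic_atlas(cfg)
    save_label_volume(atlas, outdir / "atlas.nii.gz")
    gt_spec = gt_spec if gt_spec is not None else default_gt_spec()
    cs, gt = sample_contrasts(atlas, gt_spec, jitter_mm=jitter_mm, rng_seed=cfg.rng_seed)
    write_contrast_table(cs, outdir / "contrasts.tsv")
    gt.to_json(outdir / "ground_truth.json")
    subjects = []
    for i in range(cfg.n_subjects):
        ts = simulate_subject(atlas, cfg, i)
        bold = outdir / f"sub-{i:03d}_bold.nii.gz"
        img = nib.Nifti1Image(ts.data.astype(np.float32), atlas.grid.affine)
        img.to_filename(str(bold))
        motion = outdir / f"sub-{i:03d}_motion.txt"
        np.savetxt(motion, ts.motion, fmt="%.8f")
        subjects.append([str(bold), str(motion)])
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    manifest = {
        "atlas": str(outdir / "atlas.nii.gz"),
        "contrast_table": str(outdir / "contrasts.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
        "subjects": subjects,
        "config": str(outdir / "config.yaml"),
    }
    (outdir / "dataset.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _load_file_cohort(cfg: PipelineConfig, grid: BrainGrid):
    import nibabel as nib

    for bold_path, motion_path in cfg.subjects:
        img = nib.load(str(bold_path))
        data = np.asarray(img.dataobj, dtype=float)
        motion = load_motion_parameters(motion_path, data.shape[3]) if motion_path else None
        yield SubjectTimeSeries(
            grid, data, tr_s=cfg.synthetic.tr_s if cfg.synthetic else float(img.header.get_zooms()[3] or 1.0),
            motion=motion, subject_id=Path(bold_path).stem,
        )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute a configured run end to end and write all artifacts.

    Returns the run manifest (also written as ``manifest.json``): config
    hash, input checksums, per-stage counts, output paths and collected
    warnings.  Any stage failure propagates after the manifest records
    which stages completed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fcnm_version": _version,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_jsonable(),
        "stages": [],
        "counts": {},
        "input_checksums": {},
        "outputs": {},
        "warnings": [],
    }

    gt = None
    if cfg.synthetic is not None:
        sim = cfg.synthetic
        atlas = make_synthetic_atlas(sim)
        grid = atlas.grid
        gt_spec = [tuple(e) for e in cfg.gt_spec] if cfg.gt_spec else default_gt_spec()
        contrasts, gt = sample_contrasts(
            atlas, gt_spec, jitter_mm=cfg.jitter_mm, rng_seed=sim.rng_seed
        )
        subjects = (simulate_subject(atlas, sim, i) for i in range(sim.n_subjects))
        manifest["stages"].append("simulate")
    else:
        atlas = load_label_volume(cfg.atlas_path) if cfg.atlas_path else None
        if cfg.gm_mask_path:
            gm_vol = load_volume(cfg.gm_mask_path)
            grid = gm_vol.grid.with_gm_mask(gm_vol.values > 0.5)
        elif atlas is not None:
            grid = atlas.grid.with_gm_mask(atlas.labels > 0)
        else:
            raise InvalidArgumentError("file mode needs atlas_path or gm_mask_path")
        contrasts = parse_contrast_table(cfg.contrast_table)
        manifest["input_checksums"]["contrast_table"] = _file_checksum(cfg.contrast_table)
        subjects = _load_file_cohort(cfg, grid)

    contrasts = convert_set_to_mni(contrasts, variant=cfg.tal_variant)
    n_in = len(contrasts)
    contrasts, excl = apply_gm_filter(contrasts, grid)
    manifest["stages"].append("ingest")
    manifest["counts"]["contrasts_in"] = n_in
    manifest["counts"]["contrasts_retained"] = len(contrasts)
    manifest["counts"]["peaks_dropped"] = len(excl.dropped_peaks)
    manifest["counts"].update(
        {f"summary_{k}": v for k, v in summarize_contrast_set(contrasts).items()}
    )
    if cfg.write_volumes:
        excl.write_tsv(out / "exclusion_log.tsv")
        manifest["outputs"]["exclusion_log"] = str(out / "exclusion_log.tsv")

    result = analyze_cohort(
        contrasts,
        subjects,
        grid,
        radii=cfg.radii,
        q=cfg.q,
        prob_threshold=cfg.prob_threshold,
        inclusive_threshold=cfg.inclusive_threshold,
        one_sided=cfg.one_sided,
        preprocess_cfg=cfg.preprocess,
        atlas=atlas,
        significance_threshold=cfg.significance_threshold,
        per_modality=cfg.per_modality,
        intersect_gm=cfg.intersect_gm,
    )
    manifest["stages"] += ["seeds", "fcmaps", "group", "probability"]
    manifest["counts"]["n_subjects"] = result.n_subjects
    manifest["warnings"] += result.warnings

    for r, res in result.per_radius.items():
        tag = f"r{r:g}mm"
        manifest["counts"][f"n_network_voxels_{tag}"] = {
            cid: int(n) for cid, n in res.n_rejected.items()
        }
        manifest["counts"][f"n_dysfunctional_voxels_{tag}"] = res.dysfunctional.n_voxels
        manifest["outputs"][f"probability_map_{tag}_checksum"] = _array_checksum(
            res.prob_map.prob
        )
        if cfg.write_volumes:
            p1 = save_volume(
                Volume(grid, res.prob_map.prob), out / f"probability_map_{tag}.nii.gz"
            )
            p2 = save_volume(
                Volume(grid, res.dysfunctional.mask.astype(float)),
                out / f"dysfunctional_network_{tag}.nii.gz",
            )
            manifest["outputs"][f"probability_map_{tag}"] = str(p1)
            manifest["outputs"][f"dysfunctional_network_{tag}"] = str(p2)
            for mod, mp in res.per_modality_prob.items():
                pm_path = save_volume(
                    Volume(grid, mp.prob), out / f"probability_map_{tag}_{mod}.nii.gz"
                )
                manifest["outputs"][f"probability_map_{tag}_{mod}"] = str(pm_path)
        if res.overlap is not None:
            manifest["stages"].append(f"overlap_{tag}")
            if cfg.write_volumes:
                res.overlap.write_tsv(out / f"overlap_{tag}.tsv")
                res.overlap.write_json(out / f"overlap_{tag}.json")
                manifest["outputs"][f"overlap_{tag}"] = str(out / f"overlap_{tag}.tsv")
            manifest["counts"][f"significant_networks_{tag}"] = res.overlap.significant_networks

    if result.dice:
        manifest["counts"]["dice"] = {
            f"r{a:g}mm_vs_r{b:g}mm": round(v, 6) for (a, b), v in result.dice.items()
        }

    if gt is not None and result.per_radius:
        r0 = cfg.radii[0]
        if result.per_radius[r0].overlap is not None:
            rec = evaluate_recovery(result.per_radius[r0].overlap, gt)
            manifest["counts"]["recovery"] = {
                "target_network": rec.target_network,
                "target_proportion": round(rec.target_proportion, 6),
                "max_nontarget_proportion": round(rec.max_nontarget_proportion, 6),
                "passed": rec.passed,
            }
    manifest["stages"].append("report")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
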