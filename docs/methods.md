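# Methods notes

This note records the modelling and numerical choices behind the
package, in the order the pipeline applies them, together with what the
synthetic validation does and does not establish.

## Coordinate ingestion

The unit of analysis is the contrast (one reported between-group
comparison), not the study: a study may contribute several contrasts,
and all peaks of one contrast — regardless of effect direction — form
one seed.  Talairach-space peaks are converted to MNI with the inverse
of the Lancaster *icbm2tal* affine; the SPM-fit variant is the default
(the source literature for the motivating application was analysed in
SPM), with the pooled variant available via `variant="pooled"`.  The
Brett transform is deliberately not offered: Lancaster is the current
standard in coordinate-based meta-analysis tooling.

Peaks are mapped to voxels by rounding half away from zero, the same
rule everywhere, so integer-mm coordinates land deterministically.
Within a contrast, peaks that round to the same voxel are collapsed to
one (a duplicated row must not double-weight a voxel).  Peaks outside
the gray-matter mask are dropped and logged; a contrast losing all its
peaks is excluded, mirroring the usual exclusion rule for coordinates
outside gray matter.

The packaged `example_contrasts.tsv` reproduces the *study-level*
bookkeeping of the motivating evidence base (19 studies; PD-ICD group
sizes summing to 345; modalities SPECT/PET/task-fMRI/rs-fMRI/VBM).
The peak coordinates in it are synthetic stand-ins placed in regions
of the kind typically implicated (temporal, cingulate, angular,
caudate), because the source coordinates are not printed anywhere we
can redistribute from.  The control-group sizes are reproduced as
published even though they sum to 654 while the source abstract states
787; the table intentionally preserves the published values rather
than "fixing" them.

## Seeds

A voxel belongs to a sphere iff its center lies within the radius
(closed ball, Euclidean distance in world mm).  On a 3-mm grid a 4-mm
sphere centred on a voxel center therefore contains exactly 7 voxels
(center + 6 face neighbours at 3.0 mm; face diagonals at 4.24 mm are
outside) and a 1-mm sphere exactly 1.  Seeds are rasterised directly
on the analysis grid — not on a finer grid and resampled — to avoid an
extra interpolation step, and are intersected with the gray-matter
mask (`intersect_gm=False` disables this, since the corresponding step
of published pipelines is usually unstated).

## Denoising

Only stages that act on a voxel-by-time array are implemented; all
registration steps are out of scope and inputs are assumed to be in a
common space already.  The fixed order is: discard initial volumes
(default 10) → framewise displacement and confound assembly → OLS
confound regression → bandpass → smoothing.

- **FD** uses Power's formula with a 50-mm head radius — the variant
  that the conventional 0.5-mm spike threshold belongs to.
- **Friston-24** uses backward differences with a zero first row.
- **Bandpass** is a hard discrete-Fourier mask with exact band edges
  and zero phase (0.01–0.1 Hz default).  This deviates from the
  Butterworth designs inside SPM/DPABI on purpose: the hard mask is
  bit-reproducible across platforms and trivially characterised in
  tests.  DC is removed by construction.
- **Global-signal regression is on by default** (toggle `use_gsr`),
  with white-matter and CSF series always used when present.
- **Smoothing** converts FWHM to sigma per axis via the grid spacing
  (σ = FWHM / 2√(2 ln 2)); FWHM 6 mm default, 0 = identity.

Whether filtering should precede or follow nuisance regression is not
standardised across published pipelines; the order above is fixed and
logged, and each stage is individually callable if a different order
is wanted.

## Group inference

Fisher z values are clipped at |r| = 1 − 1e-7 before artanh — seed
voxels correlate at ~1 with the seed mean and must not overflow.  The
one-sample t-test uses the sample sd (ddof 1); voxels whose z-values
are numerically constant across subjects are treated as zero-variance
(t = +inf/p = 0 for positive mean, else t = 0/p = 1).  P-values are
one-sided (upper tail) because only positive connectivity is retained
downstream; a two-sided-then-sign variant is available via
`one_sided=False` since published descriptions are often ambiguous on
this point.  BH-FDR is applied per contrast over gray-matter voxels
only — the correction family is one contrast's t-map, not the pool of
all contrasts.

## Probability map and threshold

The 60% threshold is **inclusive** (≥ 0.60): with 25 contrasts,
15/25 is exactly 0.60 and should count; `inclusive=False` gives the
strict reading.  One probability map pools all modalities; per-modality
maps are additionally emitted whenever a modality has ≥ 2 contrasts.
Contrasts are never weighted by sample size.

## Canonical overlap

Overlap proportions are |dys ∩ network| / |network| with both counts
restricted to the analysis gray-matter mask, so numerator and
denominator live in the same domain; ≥ 10% flags a significant
association.  Atlas resampling is nearest-neighbour only (labels are
categorical), delegated to nilearn.  The synthetic atlas stands in for
the real 7-cortical + subcortical parcellation in all tests; a
real-atlas NIfTI is supplied through configuration, with the
composition of the subcortical label left to the user's atlas.

## Synthetic cohort

Each network parcel k shares a latent AR(1) course L_k (coefficient
0.3, unit innovation variance); voxel v in parcel k observes
β·L_k + ε_v with white ε_v ~ N(0, σ²), plus three small-amplitude
AR(1) "tissue" drifts (global/WM/CSF, amplitude 0.1) added to every
voxel, and random-walk motion traces (0.01 mm steps; rotation steps
divided by the 50-mm head radius so their displacement contribution
matches).  Defaults: 18×22×18 grid at 3 mm, 8 parcels of 640 voxels,
40 subjects, 150 frames at TR 0.72 s, β/σ = 0.7.  Everything is
deterministic given (seed, subject index).

This is the *minimal* structure under which seed-based network mapping
should succeed.  It does not emulate hemodynamic convolution,
physiological noise spectra, spatial noise correlation, distance-
dependent connectivity, or disease effects (the cohort plays the role
of a healthy normative sample).  Passing the recovery tests therefore
shows the pipeline's statistics behave as designed, not that real
acquisitions meet the model's assumptions.

**Scenario preprocessing.**  The reference synthetic analyses use
confound regression only (`PreprocessConfig.minimal()`), no bandpass
and no smoothing.  The generator's innovations are white, so bandpass
filtering would only induce temporal autocorrelation that the t-test's
nominal degrees of freedom do not account for, and spatial smoothing
would smear seed self-correlation into neighbouring voxels — both
would degrade the null calibration that the synthetic cohort exists to
check.  On real BOLD data the full default preprocessing applies.

## Validation scales and observed behaviour

Problem sizes were chosen so every check runs comfortably on one CPU:
the recovery/robustness scenario uses the default 40×150 cohort at
three radii; null calibration uses 20 independent zero-signal cohorts
of the same size; kernel oracles use 10 subjects on a 1000-voxel grid
and 1000 random p-vectors.

Radius robustness depends on parcel geometry: a 7-mm sphere on a 3-mm
grid spans ±2 voxels, a sizeable fraction of an 8-voxel-wide synthetic
parcel, so seeds near parcel boundaries recruit neighbouring parcels
and the 7-mm network can be visibly broader than the 4-mm one.  The
Dice(4 mm, 7 mm) statistic therefore fluctuates more across
realisations than Dice(4 mm, 1 mm); with realistically sized networks
(thousands of voxels) the spill fraction is far smaller.  The fixed-
seed robustness test reflects the default settings; the acceptance
script reports the statistic for whichever seed it is given.

## Engineering notes

Per-subject FC maps are held in memory during a run (≈ 70 MB at the
reference scale).  The cohort is streamed — subjects are generated,
denoised, correlated and released one at a time — so adding a
spill-to-disk path for connectome-scale cohorts is a local change, but
none is currently implemented.  All volumes are NIfTI-1 with the
affine in the sform; label volumes carry a JSON sidecar naming the
networks.  Run manifests record a configuration hash, per-stage
counts, warnings and content checksums of the probability maps, and
identical configurations reproduce identical checksums.
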