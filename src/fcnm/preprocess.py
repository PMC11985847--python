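"""Resting-state preprocessing for data already in a common space.

Covers the denoising stages that act on a voxel-by-time array: initial
volume discarding, motion screening, framewise displacement, confound
regression (linear drift, Friston-24 motion expansion, FD spike
regressors, global/white-matter/CSF signals), bandpass filtering and
Gaussian smoothing.  Registration-type steps (slice timing, realignment
estimation, segmentation, nonlinear normalisation) are out of scope:
inputs are assumed resampled to the analysis grid already.

The canonical order, applied by :func:`preprocess_subject`, is
discard -> (FD, confounds) -> regression -> bandpass -> smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import (
    DegenerateDesignError,
    GridMismatchError,
    InvalidArgumentError,
    MissingDataError,
)
from .grids import BrainGrid, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectTimeSeries",
    "ConfoundMatrix",
    "MotionCheck",
    "PreprocessConfig",
    "discard_initial_volumes",
    "framewise_displacement",
    "motion_exclusion_check",
    "build_confound_matrix",
    "regress_confounds",
    "bandpass_filter",
    "gaussian_smooth",
    "preprocess_subject",
    "load_motion_parameters",
]

#: Assumed head radius (mm) converting rotations to displacements in the
#: Power framewise-displacement formula.
FD_HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's 4D data on a grid, plus acquisition metadata.

    ``data`` has shape ``grid.shape + (T,)``; ``motion`` (optional) is
    ``(T, 6)`` — three translations in mm then three rotations in
    radians; ``tissue_signals`` (optional) maps names like ``global``,
    ``white_matter``, ``csf`` to length-T series.
    """

    grid: BrainGrid
    data: np.ndarray
    tr_s: float
    motion: np.ndarray = None
    tissue_signals: dict = None
    subject_id: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape[:3] != self.grid.shape or data.ndim != 4:
            raise GridMismatchError(
                f"data shape {data.shape} incompatible with grid {self.grid.shape}"
            )
        if data.shape[3] < 2:
            raise InvalidArgumentError("need at least 2 timepoints")
        if float(self.tr_s) <= 0:
            raise InvalidArgumentError("tr_s must be positive")
        if self.motion is not None:
            motion = np.asarray(self.motion, dtype=float)
            if motion.shape != (data.shape[3], 6):
                raise InvalidArgumentError(
                    f"motion shape {motion.shape} != ({data.shape[3]}, 6)"
                )
            object.__setattr__(self, "motion", motion)
        if self.tissue_signals is not None:
            ts = {str(k): np.asarray(v, dtype=float) for k, v in self.tissue_signals.items()}
            for k, v in ts.items():
                if v.shape != (data.shape[3],):
                    raise InvalidArgumentError(f"tissue signal {k!r} has wrong length")
            object.__setattr__(self, "tissue_signals", ts)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "tr_s", float(self.tr_s))

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class ConfoundMatrix:
    """Named per-timepoint nuisance regressors."""

    frame: pd.DataFrame

    def __post_init__(self):
        if self.frame.columns.duplicated().any():
            raise InvalidArgumentError("duplicate confound column names")

    @property
    def names(self):
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __len__(self):
        return len(self.frame)


@dataclass(frozen=True)
class MotionCheck:
    passed: bool
    max_translation_mm: float
    max_rotation_deg: float
    offenders: tuple  # (frame, parameter, value) of worst violations


def discard_initial_volumes(ts: SubjectTimeSeries, n_discard: int = 10) -> SubjectTimeSeries:
    """Drop the first ``n_discard`` frames (signal-equilibration dummies)
    from data, motion and tissue signals alike."""
    n = int(n_discard)
    if n < 0:
        raise InvalidArgumentError("n_discard must be >= 0")
    if n == 0:
        return ts
    if n >= ts.n_timepoints:
        raise InvalidArgumentError(
            f"cannot discard {n} of {ts.n_timepoints} frames"
        )
    return replace(
        ts,
        data=ts.data[..., n:],
        motion=None if ts.motion is None else ts.motion[n:],
        tissue_signals=None
        if ts.tissue_signals is None
        else {k: v[n:] for k, v in ts.tissue_signals.items()},
    )


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power framewise displacement, mm per frame (first frame 0).

    FD(t) = sum |Δtranslation_i| + r * sum |Δrotation_i| with rotations
    in radians projected onto a sphere of radius r = 50 mm.
    """
    if motion is None:
        raise MissingDataError("motion parameters are required for FD")
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise InvalidArgumentError("motion must be (T>=2, 6)")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def motion_exclusion_check(
    motion: np.ndarray, max_translation_mm: float = 2.0, max_rotation_deg: float = 2.0
) -> MotionCheck:
    """Screen a motion trace against the usual inclusion rule.

    A subject passes only if every translation stays strictly below
    ``max_translation_mm`` and every rotation strictly below
    ``max_rotation_deg`` (rotations stored in radians, compared in
    degrees); hitting the threshold exactly fails.
    """
    if motion is None:
        raise MissingDataError("motion parameters are required")
    motion = np.asarray(motion, dtype=float)
    trans = np.abs(motion[:, :3])
    rot_deg = np.degrees(np.abs(motion[:, 3:]))
    passed = bool(trans.max() < max_translation_mm and rot_deg.max() < max_rotation_deg)
    offenders = []
    for t, p in zip(*np.where(trans >= max_translation_mm)):
        offenders.append((int(t), f"trans_{'xyz'[p]}", float(motion[t, p])))
    for t, p in zip(*np.where(rot_deg >= max_rotation_deg)):
        offenders.append((int(t), f"rot_{'xyz'[p]}", float(rot_deg[t, p])))
    return MotionCheck(passed, float(trans.max()), float(rot_deg.max()), tuple(offenders))


def _friston24(motion: np.ndarray) -> pd.DataFrame:
    """6 motion params, their one-lag backward differences (zero first
    row), and the squares of both — 24 columns."""
    names6 = ["tx", "ty", "tz", "rx", "ry", "rz"]
    diff = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols = {}
    for j, n in enumerate(names6):
        cols[f"mot_{n}"] = motion[:, j]
    for j, n in enumerate(names6):
        cols[f"mot_d{n}"] = diff[:, j]
    for j, n in enumerate(names6):
        cols[f"mot_{n}_sq"] = motion[:, j] ** 2
    for j, n in enumerate(names6):
        cols[f"mot_d{n}_sq"] = diff[:, j] ** 2
    return pd.DataFrame(cols)


def build_confound_matrix(
    ts: SubjectTimeSeries,
    fd: np.ndarray = None,
    fd_spike_mm: float = 0.5,
    use_motion: bool = True,
    use_gsr: bool = True,
    use_drift: bool = True,
) -> ConfoundMatrix:
    """Assemble the nuisance design: intercept, linear drift, Friston-24
    motion expansion, FD>threshold spike indicators, and tissue signals.

    Global signal is included by default (``use_gsr``); white-matter and
    CSF series are always used when present.  All-zero columns are
    pruned with a warning.  If every frame is a spike the design is
    unusable and :class:`DegenerateDesignError` is raised.
    """
    T = ts.n_timepoints
    parts = [pd.DataFrame({"intercept": np.ones(T)})]
    if use_drift:
        parts.append(pd.DataFrame({"drift": np.linspace(0.0, 1.0, T)}))
    if use_motion:
        if ts.motion is None:
            raise MissingDataError("Friston-24 confounds need motion parameters")
        parts.append(_friston24(ts.motion))
    if fd is None and ts.motion is not None:
        fd = framewise_displacement(ts.motion)
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.shape != (T,):
            raise InvalidArgumentError("fd length does not match timepoints")
        spikes = np.flatnonzero(fd > fd_spike_mm)
        if spikes.size == T:
            raise DegenerateDesignError("every frame exceeds the FD spike threshold")
        spike_cols = {}
        for t in spikes:
            col = np.zeros(T)
            col[t] = 1.0
            spike_cols[f"spike_{int(t):04d}"] = col
        if spike_cols:
            parts.append(pd.DataFrame(spike_cols))
    if ts.tissue_signals:
        tissue = {
            k: v
            for k, v in ts.tissue_signals.items()
            if use_gsr or k != "global"
        }
        if tissue:
            parts.append(pd.DataFrame({f"tissue_{k}": v for k, v in tissue.items()}))
    frame = pd.concat(parts, axis=1)
    zero = [c for c in frame.columns if c != "intercept" and not frame[c].any()]
    if zero:
        logger.warning("pruning all-zero confound column(s): %s", zero)
        frame = frame.drop(columns=zero)
    return ConfoundMatrix(frame)


def regress_confounds(ts: SubjectTimeSeries, cm: ConfoundMatrix) -> SubjectTimeSeries:
    """Replace the data with per-voxel OLS residuals against the design.

    Uses a least-squares solve per voxel (vectorised); rank-deficient
    designs fall back to the pseudo-inverse with a logged warning.
    Residuals are orthogonal to every confound column.
    """
    X = cm.values
    T = ts.n_timepoints
    if len(cm) != T:
        raise InvalidArgumentError("confound rows do not match timepoints")
    if X.shape[1] >= T:
        raise InvalidArgumentError(
            f"{X.shape[1]} confounds for {T} timepoints leaves no residual df"
        )
    Y = ts.data.reshape(-1, T).T  # (T, nvox)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "confound design rank-deficient (rank %d < %d columns); pseudo-inverse used",
            rank,
            X.shape[1],
        )
    resid = Y - X @ beta
    return replace(ts, data=resid.T.reshape(ts.data.shape))


def bandpass_filter(ts: SubjectTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> SubjectTimeSeries:
    """Zero-phase bandpass via a hard discrete-Fourier mask.

    Frequencies f with low_hz <= f <= high_hz are retained exactly and
    everything else (including DC) is zeroed.  A hard spectral cut is
    used deliberately: it is platform-reproducible and has exact
    passband edges, unlike IIR designs.
    """
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise InvalidArgumentError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:.4f} Hz"
        )
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=ts.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(ts.data, axis=-1)
    spectrum[..., ~keep] = 0.0
    return replace(ts, data=np.fft.irfft(spectrum, n=T, axis=-1))


def _fwhm_to_sigma_vox(fwhm_mm: float, grid: BrainGrid) -> np.ndarray:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return sigma_mm / grid.spacing


def gaussian_smooth(obj, fwhm_mm: float = 6.0):
    """3D Gaussian smoothing of a Volume or of each frame of a
    SubjectTimeSeries; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise InvalidArgumentError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return obj
    if isinstance(obj, Volume):
        sigma = _fwhm_to_sigma_vox(fwhm_mm, obj.grid)
        return Volume(obj.grid, ndi.gaussian_filter(obj.values, sigma=sigma))
    if isinstance(obj, SubjectTimeSeries):
        sigma = tuple(_fwhm_to_sigma_vox(fwhm_mm, obj.grid)) + (0.0,)
        return replace(obj, data=ndi.gaussian_filter(obj.data, sigma=sigma))
    raise InvalidArgumentError(f"cannot smooth object of type {type(obj).__name__}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Denoising configuration; defaults mirror a standard DPABI-style
    resting-state stream (10 dummies, FD>0.5 mm spikes, Friston-24,
    global-signal regression, 0.01-0.1 Hz band, 6 mm FWHM)."""

    n_discard: int = 10
    fd_spike_mm: float = 0.5
    use_motion: bool = True
    use_gsr: bool = True
    use_drift: bool = True
    band: tuple = (0.01, 0.1)  # None disables filtering
    fwhm_mm: float = 6.0  # 0 disables smoothing

    @classmethod
    def minimal(cls) -> "PreprocessConfig":
        """Confound regression only — no discard/filter/smooth.

        Appropriate when the input series are already stationary and
        unsmoothed, e.g. the synthetic cohorts of :mod:`fcnm.simulate`.
        """
        return cls(n_discard=0, band=None, fwhm_mm=0.0)


def preprocess_subject(ts: SubjectTimeSeries, cfg: PreprocessConfig = None) -> SubjectTimeSeries:
    """Run the fixed denoising order:
    discard -> (FD, confound build) -> regression -> bandpass -> smooth."""
    cfg = cfg or PreprocessConfig()
    ts = discard_initial_volumes(ts, cfg.n_discard)
    fd = framewise_displacement(ts.motion) if ts.motion is not None else None
    cm = build_confound_matrix(
        ts,
        fd=fd,
        fd_spike_mm=cfg.fd_spike_mm,
        use_motion=cfg.use_motion and ts.motion is not None,
        use_gsr=cfg.use_gsr,
        use_drift=cfg.use_drift,
    )
    ts = regress_confounds(ts, cm)
    if cfg.band is not None:
        ts = bandpass_filter(ts, *cfg.band)
    if cfg.fwhm_mm:
        ts = gaussian_smooth(ts, cfg.fwhm_mm)
    return ts


def load_motion_parameters(path, n_timepoints: int = None) -> np.ndarray:
    """Read whitespace-delimited motion parameters: 6 columns per frame,
    translations in mm then rotations in radians."""
    arr = np.loadtxt(path, dtype=float, ndmin=2)
    if arr.shape[1] != 6:
        raise InvalidArgumentError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    if n_timepoints is not None and arr.shape[0] != n_timepoints:
        raise InvalidArgumentError(
            f"{path}: {arr.shape[0]} rows != {n_timepoints} timepoints"
        )
    return arr
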