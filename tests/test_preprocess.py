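"""Denoising stages: discarding, FD, confounds, regression, filters."""

import logging

import numpy as np
import pytest

from fcnm.errors import (
    DegenerateDesignError,
    InvalidArgumentError,
    MissingDataError,
)
from fcnm.grids import Volume, make_grid
from fcnm.preprocess import (
    PreprocessConfig,
    SubjectTimeSeries,
    bandpass_filter,
    build_confound_matrix,
    discard_initial_volumes,
    framewise_displacement,
    gaussian_smooth,
    motion_exclusion_check,
    preprocess_subject,
    regress_confounds,
)


def _ts(rng, T=110, shape=(4, 4, 4), motion=True, tissue=True, tr=0.72):
    grid = make_grid(shape, (3, 3, 3))
    data = rng.standard_normal(shape + (T,))
    if motion:
        steps = rng.standard_normal((T, 6))
        steps[:, :3] *= 0.01  # mm
        steps[:, 3:] *= 0.0002  # rad
        mot = np.cumsum(steps, axis=0)
    else:
        mot = None
    tis = (
        {k: rng.standard_normal(T) for k in ("global", "white_matter", "csf")}
        if tissue
        else None
    )
    return SubjectTimeSeries(grid, data, tr, motion=mot, tissue_signals=tis)


class TestDiscard:
    def test_ten_of_110_leaves_100(self, rng):
        ts = _ts(rng, T=110)
        out = discard_initial_volumes(ts, 10)
        assert out.n_timepoints == 100
        assert out.motion.shape == (100, 6)
        assert out.tissue_signals["csf"].shape == (100,)
        assert np.array_equal(out.data, ts.data[..., 10:])

    def test_zero_is_identity(self, rng):
        ts = _ts(rng)
        assert discard_initial_volumes(ts, 0) is ts

    def test_discarding_everything_rejected(self, rng):
        ts = _ts(rng, T=5)
        with pytest.raises(InvalidArgumentError):
            discard_initial_volumes(ts, 10)


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        fd = framewise_displacement(np.zeros((20, 6)))
        assert np.all(fd == 0)

    def test_translation_only_hand_value(self):
        motion = np.zeros((2, 6))
        motion[1, :3] = (0.1, 0.2, 0.2)
        assert framewise_displacement(motion)[1] == pytest.approx(0.5)

    def test_rotation_scaled_by_head_radius(self):
        motion = np.zeros((2, 6))
        motion[1, 3] = 0.01  # rad
        assert framewise_displacement(motion)[1] == pytest.approx(0.5)

    def test_first_frame_is_zero(self, rng):
        fd = framewise_displacement(rng.standard_normal((10, 6)))
        assert fd[0] == 0.0

    def test_missing_motion_raises(self):
        with pytest.raises(MissingDataError):
            framewise_displacement(None)


class TestMotionExclusion:
    def test_large_translation_fails(self):
        m = np.zeros((10, 6))
        m[4, 0] = 2.5
        check = motion_exclusion_check(m)
        assert not check.passed
        assert check.max_translation_mm == 2.5
        assert ("trans_x" in [o[1] for o in check.offenders])

    def test_zero_motion_passes(self):
        assert motion_exclusion_check(np.zeros((10, 6))).passed

    def test_exactly_two_degrees_fails(self):
        m = np.zeros((10, 6))
        m[0, 4] = np.deg2rad(2.0)
        assert not motion_exclusion_check(m).passed


class TestConfoundMatrix:
    def test_full_design_has_29_columns(self, rng):
        """intercept + drift + Friston-24 + 3 tissue signals, no spikes."""
        ts = _ts(rng, T=50)
        fd = np.zeros(50)
        cm = build_confound_matrix(ts, fd=fd)
        assert len(cm.names) == 29

    def test_spike_indicator_columns(self, rng):
        ts = _ts(rng, T=3, motion=False, tissue=False)
        cm = build_confound_matrix(ts, fd=np.array([0.0, 0.6, 0.2]), use_motion=False)
        spikes = [n for n in cm.names if n.startswith("spike_")]
        assert spikes == ["spike_0001"]
        assert list(cm.frame["spike_0001"]) == [0.0, 1.0, 0.0]

    def test_all_zero_motion_columns_pruned_with_warning(self, rng, caplog):
        ts = _ts(rng, T=30, tissue=False)
        ts = SubjectTimeSeries(ts.grid, ts.data, ts.tr_s, motion=np.zeros((30, 6)))
        with caplog.at_level(logging.WARNING, logger="fcnm.preprocess"):
            cm = build_confound_matrix(ts, fd=np.zeros(30))
        assert not any(n.startswith("mot_") for n in cm.names)
        assert "pruning" in caplog.text

    def test_all_frames_spiking_is_degenerate(self, rng):
        ts = _ts(rng, T=10, motion=False, tissue=False)
        with pytest.raises(DegenerateDesignError):
            build_confound_matrix(ts, fd=np.full(10, 1.0), use_motion=False)


class TestRegression:
    def test_confound_column_regresses_to_zero(self, rng):
        ts = _ts(rng, T=40, motion=False, tissue=True)
        cm = build_confound_matrix(ts, fd=np.zeros(40), use_motion=False)
        data = ts.data.copy()
        data[0, 0, 0, :] = ts.tissue_signals["global"]
        ts = SubjectTimeSeries(ts.grid, data, ts.tr_s, tissue_signals=ts.tissue_signals)
        out = regress_confounds(ts, cm)
        assert np.allclose(out.data[0, 0, 0], 0.0, atol=1e-10)

    def test_intercept_only_demeans(self, rng):
        import pandas as pd

        from fcnm.preprocess import ConfoundMatrix

        ts = _ts(rng, T=30, motion=False, tissue=False)
        cm = ConfoundMatrix(pd.DataFrame({"intercept": np.ones(30)}))
        out = regress_confounds(ts, cm)
        expected = ts.data - ts.data.mean(axis=-1, keepdims=True)
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        """Independent OLS oracle: beta = (X'X)^-1 X'y per voxel."""
        ts = _ts(rng, T=60)
        cm = build_confound_matrix(ts)
        out = regress_confounds(ts, cm)
        X = cm.values
        y = ts.data[1, 2, 3]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(out.data[1, 2, 3], y - X @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        ts = _ts(rng, T=60)
        cm = build_confound_matrix(ts)
        out = regress_confounds(ts, cm)
        X = cm.values
        X_std = X / np.maximum(np.linalg.norm(X, axis=0), 1e-12)
        resid = out.data.reshape(-1, 60)[::7].T
        assert np.abs(X_std.T @ resid).max() < 1e-8

    def test_too_many_confounds_rejected(self, rng):
        ts = _ts(rng, T=20)
        import pandas as pd

        from fcnm.preprocess import ConfoundMatrix

        cm = ConfoundMatrix(pd.DataFrame(rng.standard_normal((20, 20)),
                                         columns=[f"c{i}" for i in range(20)]))
        with pytest.raises(InvalidArgumentError):
            regress_confounds(ts, cm)


class TestBandpass:
    def test_constant_series_removed(self, rng):
        ts = _ts(rng, T=100, motion=False, tissue=False)
        ts = SubjectTimeSeries(ts.grid, np.ones(ts.data.shape) * 5.0, ts.tr_s)
        out = bandpass_filter(ts, 0.01, 0.1)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    @pytest.mark.parametrize("freq,kept", [(0.05, True), (0.3, False)])
    def test_passband_edges(self, freq, kept):
        T, tr = 200, 0.72
        t = np.arange(T) * tr
        # Use an exact DFT bin so amplitude is measured cleanly.
        bin_freq = round(freq * T * tr) / (T * tr)
        sig = np.sin(2 * np.pi * bin_freq * t)
        grid = make_grid((1, 1, 1), (3, 3, 3))
        ts = SubjectTimeSeries(grid, sig.reshape(1, 1, 1, T), tr)
        out = bandpass_filter(ts, 0.01, 0.1).data.ravel()
        ratio = np.linalg.norm(out) / np.linalg.norm(sig)
        assert (ratio >= 0.99) if kept else (ratio <= 0.01)

    def test_band_outside_nyquist_rejected(self, rng):
        ts = _ts(rng, T=50, tr=2.0)  # Nyquist 0.25 Hz
        with pytest.raises(InvalidArgumentError):
            bandpass_filter(ts, 0.01, 0.3)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng, grid3mm):
        vol = Volume(grid3mm, rng.standard_normal(grid3mm.shape))
        assert gaussian_smooth(vol, 0.0) is vol

    def test_impulse_center_matches_kernel_oracle(self, grid3mm):
        """The response to a unit impulse equals an explicitly built,
        normalised discrete Gaussian kernel."""
        vals = np.zeros(grid3mm.shape)
        vals[5, 5, 5] = 1.0
        out = gaussian_smooth(Volume(grid3mm, vals), 6.0).values
        sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        radius = int(4 * sigma_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma_vox) ** 2)
        k1 /= k1.sum()
        k3 = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        assert out[5, 5, 5] == pytest.approx(k3[radius, radius, radius], rel=1e-6)

    def test_constant_volume_preserved_in_interior(self, grid3mm):
        out = gaussian_smooth(Volume(grid3mm, np.full(grid3mm.shape, 3.0)), 6.0)
        assert np.allclose(out.values, 3.0, atol=1e-10)

    def test_negative_fwhm_rejected(self, grid3mm):
        with pytest.raises(InvalidArgumentError):
            gaussian_smooth(Volume(grid3mm, np.zeros(grid3mm.shape)), -1.0)


class TestPipelineOrder:
    def test_rerun_is_bit_identical(self, rng):
        ts = _ts(rng, T=110)
        cfg = PreprocessConfig()
        a = preprocess_subject(ts, cfg)
        b = preprocess_subject(ts, cfg)
        assert np.array_equal(a.data, b.data)
        assert a.n_timepoints == 100

    def test_minimal_config_skips_discard_filter_smooth(self, rng):
        ts = _ts(rng, T=40)
        out = preprocess_subject(ts, PreprocessConfig.minimal())
        assert out.n_timepoints == 40
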