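"""Seed FC maps, Fisher z, group t-tests and BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fcnm.connectivity import (
    FCMap,
    FISHER_CLIP,
    binarize_positive,
    fc_zmap,
    fdr_bh,
    fisher_z,
    group_tmap,
    seed_timecourse,
)
from fcnm.errors import (
    DegenerateSeedError,
    GridMismatchError,
    InsufficientDataError,
    InvalidArgumentError,
)
from fcnm.grids import make_grid
from fcnm.preprocess import SubjectTimeSeries
from fcnm.seeds import SeedMask


def _subject(rng, grid, T=80):
    return SubjectTimeSeries(grid, rng.standard_normal(grid.shape + (T,)), 0.72)


def _seed(grid, voxels):
    mask = np.zeros(grid.shape, bool)
    for v in voxels:
        mask[v] = True
    return SeedMask(grid, mask, "c", 4.0)


class TestSeedTimecourse:
    def test_single_voxel_seed_returns_that_series(self, rng, grid3mm):
        ts = _subject(rng, grid3mm)
        course = seed_timecourse(ts, _seed(grid3mm, [(2, 3, 4)]))
        assert np.array_equal(course, ts.data[2, 3, 4])

    def test_opposite_series_cancel(self, rng, grid3mm):
        ts = _subject(rng, grid3mm)
        data = ts.data.copy()
        data[1, 1, 1] = -data[0, 0, 0]
        ts = SubjectTimeSeries(grid3mm, data, 0.72)
        course = seed_timecourse(ts, _seed(grid3mm, [(0, 0, 0), (1, 1, 1)]))
        assert np.allclose(course, 0.0)

    def test_matches_bruteforce_mean(self, rng, grid3mm):
        ts = _subject(rng, grid3mm)
        voxels = [(0, 1, 2), (3, 3, 3), (9, 9, 9), (5, 2, 7), (4, 4, 4)]
        course = seed_timecourse(ts, _seed(grid3mm, voxels))
        manual = sum(ts.data[v] for v in voxels) / 5.0
        assert np.allclose(course, manual, atol=1e-12)

    def test_grid_mismatch(self, rng, grid3mm):
        other = make_grid((10, 10, 10), (2, 2, 2))
        ts = _subject(rng, grid3mm)
        with pytest.raises(GridMismatchError):
            seed_timecourse(ts, _seed(other, [(0, 0, 0)]))


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)
        assert fisher_z(-0.5) == pytest.approx(-0.5493061443340549, abs=1e-12)

    def test_clipping_keeps_transform_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(FISHER_CLIP))

    def test_magnitude_above_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fisher_z(1.5)


class TestFCZmap:
    def test_voxel_equal_to_seed_course_hits_clip_ceiling(self, rng, grid3mm):
        ts = _subject(rng, grid3mm)
        fc = fc_zmap(ts, _seed(grid3mm, [(4, 4, 4)]))
        assert fc.z_values[4, 4, 4] == pytest.approx(np.arctanh(FISHER_CLIP))

    def test_independent_noise_z_is_small(self, rng):
        grid = make_grid((8, 8, 8), (3, 3, 3))
        ts = SubjectTimeSeries(grid, rng.standard_normal(grid.shape + (200,)), 0.72)
        fc = fc_zmap(ts, _seed(grid, [(0, 0, 0)]))
        z = fc.z_values[grid.gm_mask]
        z = z[np.abs(z) < 1.0]  # drop the seed voxel itself
        # z ~ N(0, 1/sqrt(T-3)): |z| < 0.3 is ~4.2 sd at T=200
        assert np.mean(np.abs(z) < 0.3) > 0.995

    def test_matches_bruteforce_correlation_oracle(self, rng):
        grid = make_grid((5, 5, 5), (3, 3, 3))
        ts = _subject(rng, grid, T=40)
        seed = _seed(grid, [(0, 0, 0), (1, 2, 3), (4, 4, 4)])
        fc = fc_zmap(ts, seed)
        course = ts.data[seed.mask].mean(axis=0)
        worst = 0.0
        for ijk in np.ndindex(*grid.shape):
            r = np.corrcoef(course, ts.data[ijk])[0, 1]
            expected = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
            worst = max(worst, abs(fc.z_values[ijk] - expected))
        assert worst <= 1e-10

    def test_zero_variance_voxels_get_zero(self, rng, grid3mm):
        ts = _subject(rng, grid3mm)
        data = ts.data.copy()
        data[7, 7, 7] = 2.5
        ts = SubjectTimeSeries(grid3mm, data, 0.72)
        fc = fc_zmap(ts, _seed(grid3mm, [(0, 0, 0)]))
        assert fc.z_values[7, 7, 7] == 0.0

    def test_constant_seed_course_raises(self, grid3mm, rng):
        data = rng.standard_normal(grid3mm.shape + (30,))
        data[0, 0, 0] = 1.0
        ts = SubjectTimeSeries(grid3mm, data, 0.72)
        with pytest.raises(DegenerateSeedError):
            fc_zmap(ts, _seed(grid3mm, [(0, 0, 0)]))


class TestGroupTMap:
    def test_hand_computed_t(self, grid3mm):
        maps = [
            FCMap(grid3mm, np.full(grid3mm.shape, v)) for v in (0.1, 0.2, 0.3)
        ]
        tm = group_tmap(maps)
        assert tm.df == 2
        assert tm.t[0, 0, 0] == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-10)
        assert tm.t[0, 0, 0] == pytest.approx(3.4641016, abs=1e-6)

    def test_all_zero_maps(self, grid3mm):
        tm = group_tmap([FCMap(grid3mm, np.zeros(grid3mm.shape)) for _ in range(4)])
        assert np.all(tm.t == 0) and np.all(tm.p == 1)

    def test_zero_variance_positive_mean(self, grid3mm):
        tm = group_tmap([FCMap(grid3mm, np.full(grid3mm.shape, 0.4)) for _ in range(3)])
        assert np.all(np.isposinf(tm.t)) and np.all(tm.p == 0)

    def test_matches_textbook_formula_oracle(self, rng, grid3mm):
        Z = rng.standard_normal((8,) + grid3mm.shape)
        tm = group_tmap([FCMap(grid3mm, z) for z in Z])
        mean = Z.mean(axis=0)
        sd = np.sqrt(((Z - mean) ** 2).sum(axis=0) / 7)
        t_expected = mean / (sd / np.sqrt(8))
        assert np.abs(tm.t - t_expected).max() <= 1e-10
        assert np.allclose(tm.p, stats.t.sf(t_expected, 7), atol=1e-12)

    def test_single_map_is_insufficient(self, grid3mm):
        with pytest.raises(InsufficientDataError):
            group_tmap([FCMap(grid3mm, np.zeros(grid3mm.shape))])


def naive_bh(p, q):
    """O(m^2) step-up oracle: reject all p <= the largest candidate
    threshold t in p with t <= count(p <= t) * q / m."""
    p = np.asarray(p)
    m = p.size
    counts = (p[None, :] <= p[:, None]).sum(axis=1)
    valid = p[p <= counts * q / m]
    if valid.size == 0:
        return np.zeros(m, bool)
    return p <= valid.max()


class TestFdrBH:
    def test_hand_stepup_example(self):
        rej = fdr_bh(np.array([0.01, 0.02, 0.04, 0.5]), 0.05)
        assert list(rej) == [True, True, False, False]

    def test_all_ones_rejects_nothing(self):
        assert not fdr_bh(np.ones(50), 0.05).any()

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fdr_bh(np.array([]), 0.05)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ours = fdr_bh(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), q=st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_naive_quadratic_oracle(self, seed, q):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 300))
        if rng.random() < 0.3:  # exercise ties
            p = np.round(p, 2)
        assert np.array_equal(fdr_bh(p, q), naive_bh(p, q))

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_q(self, seed):
        """Lowering q never adds rejections."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=100)
        hi = fdr_bh(p, 0.10)
        lo = fdr_bh(p, 0.02)
        assert not (lo & ~hi).any()


class TestBinarizePositive:
    def test_negative_t_excluded_even_if_rejected(self, grid3mm):
        t = np.full(grid3mm.shape, -3.0)
        t[0, 0, 0] = 3.0
        tm = type("TM", (), {})  # light stand-in is clumsy; build real map
        from fcnm.connectivity import GroupTMap

        tm = GroupTMap(grid3mm, t, np.full(grid3mm.shape, 0.001), 10)
        rejected = np.ones(grid3mm.shape, bool)
        bn = binarize_positive(tm, rejected)
        assert bn.mask[0, 0, 0]
        assert bn.n_voxels == 1

    def test_no_rejections_gives_empty_map(self, grid3mm):
        from fcnm.connectivity import GroupTMap

        tm = GroupTMap(grid3mm, np.ones(grid3mm.shape), np.full(grid3mm.shape, 0.5), 5)
        bn = binarize_positive(tm, np.zeros(grid3mm.shape, bool))
        assert bn.n_voxels == 0

    def test_mask_restricted_to_gray_matter(self, grid3mm):
        from fcnm.connectivity import GroupTMap

        gm = np.zeros(grid3mm.shape, bool)
        gm[:5] = True
        grid = grid3mm.with_gm_mask(gm)
        tm = GroupTMap(grid, np.full(grid.shape, 4.0), np.zeros(grid.shape), 5)
        bn = binarize_positive(tm, np.ones(grid.shape, bool))
        assert not (bn.mask & ~gm).any()
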