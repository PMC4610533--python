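import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbcseg.morphology import connected_components
from wbcseg.synth import SceneSpec, apply_illumination, make_smear
from wbcseg.wbc_region import (
    MeanShiftConfig,
    adaptive_threshold_fraction,
    build_outside_seeds,
    mean_shift_filter,
    wbc_cluster_mask,
    wbc_enhanced_mask,
)


from .oracles import mean_shift_oracle


class TestMeanShift:
    def test_constant_plane_unchanged(self):
        plane = np.full((12, 12), 77.0)
        np.testing.assert_array_equal(mean_shift_filter(plane), plane)

    def test_well_separated_regions_untouched(self):
        plane = np.full((10, 20), 40.0)
        plane[:, 10:] = 200.0
        out = mean_shift_filter(plane, MeanShiftConfig(hs=3, hr=3.0))
        np.testing.assert_array_equal(out, plane)

    def test_outlier_pulled_into_mode(self):
        plane = np.full((9, 9), 98.0)
        plane[4, 4] = 100.0
        out = mean_shift_filter(plane, MeanShiftConfig(hs=3, hr=3.0))
        assert 97.0 <= out[4, 4] <= 99.0

    def test_contraction_on_intensity_range(self, rng):
        plane = rng.integers(0, 256, size=(24, 24)).astype(float)
        out = mean_shift_filter(plane)
        assert out.min() >= plane.min() - 1e-12
        assert out.max() <= plane.max() + 1e-12

    def test_exact_oracle_agreement(self, rng):
        cfg = MeanShiftConfig(hs=3, hr=3.0, max_iters=4, convergence_tol=0.5)
        for _ in range(5):
            plane = rng.integers(0, 256, size=(16, 16)).astype(float)
            got = mean_shift_filter(plane, cfg)
            want = mean_shift_oracle(plane, cfg.hs, cfg.hr, cfg.max_iters,
                                     cfg.convergence_tol)
            np.testing.assert_array_equal(got, want)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MeanShiftConfig(hs=0)
        with pytest.raises(ValueError):
            MeanShiftConfig(hr=0)


class TestAdaptiveThreshold:
    def test_bimodal_fraction(self):
        plane = np.zeros((100, 100))
        plane[:30] = 200.0
        plane[30:] = 10.0
        # nucleus 10% of image, N=3 -> background budget 70% -> Tg = 10
        t = adaptive_threshold_fraction(plane, 0.1 * plane.size, 3.0)
        assert t == 10
        assert (plane > t).sum() == 3000

    def test_zero_nucleus_empty_foreground(self, rng):
        plane = rng.integers(0, 256, size=(32, 32)).astype(float)
        t = adaptive_threshold_fraction(plane, 0, 3.0)
        assert not (plane > t).any()

    def test_overbudget_warns_full_foreground(self):
        plane = np.full((10, 10), 128.0)
        with pytest.warns(UserWarning):
            t = adaptive_threshold_fraction(plane, 80, 3.0)
        assert t == 0

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.floats(min_value=0, max_value=0.3),
           st.floats(min_value=1.1, max_value=4.0),
           st.floats(min_value=0, max_value=0.2))
    def test_monotone_in_nucleus_area_and_ratio(self, seed, frac, n_ratio, bump):
        rng = np.random.default_rng(seed)
        plane = rng.integers(0, 256, size=(16, 16)).astype(float)
        area = frac * plane.size
        t0 = adaptive_threshold_fraction(plane, area, n_ratio)
        t1 = adaptive_threshold_fraction(plane, area + bump * plane.size, n_ratio)
        t2 = adaptive_threshold_fraction(plane, area, n_ratio + 0.5)
        assert t1 <= t0 and t2 <= t0

    def test_foreground_fraction_tie_bound(self, rng):
        """Foreground can overshoot the N*Sn budget by at most the mass of
        one histogram bin (the tie bin at the threshold)."""
        for _ in range(20):
            plane = rng.integers(0, 32, size=(20, 20)).astype(float) * 8
            area = float(rng.integers(0, 60))
            n_ratio = float(rng.uniform(1.2, 4))
            t = adaptive_threshold_fraction(plane, area, n_ratio)
            fg = (plane > t).sum()
            largest_bin = np.bincount(plane.astype(int).ravel()).max()
            assert fg <= n_ratio * area + largest_bin


class TestStrategyMasks:
    def test_cluster_mask_covers_cells(self, params, simple_scene):
        img, gt = simple_scene
        nucleus_area = (gt.nucleus_labels > 0).sum()
        mask = wbc_cluster_mask(img, nucleus_area, params)
        for i in range(1, gt.n_cells + 1):
            cell = gt.wbc_labels == i
            assert (mask & cell).sum() / cell.sum() >= 0.6

    def test_bandwidths_change_mask(self, params, simple_scene):
        img, gt = simple_scene
        na = (gt.nucleus_labels > 0).sum()
        base = wbc_cluster_mask(img, na, params)
        wide = wbc_cluster_mask(img, na, params.replace(hs=1, hr=13.0))
        tall = wbc_cluster_mask(img, na, params.replace(hs=13, hr=1.0))
        assert (base ^ wide).any() or (base ^ tall).any()

    def test_wbc_free_image_empty(self, params, empty_scene):
        img, _ = empty_scene
        assert not wbc_cluster_mask(img, 0, params).any()

    def test_enhanced_mask_separates_wbc(self, params, simple_scene):
        img, gt = simple_scene
        na = (gt.nucleus_labels > 0).sum()
        mask = wbc_enhanced_mask(img, na, params)
        wbc = gt.wbc_labels > 0
        assert (mask & wbc).sum() / wbc.sum() >= 0.8
        assert (mask & ~wbc).sum() <= 0.05 * (~wbc).sum()

    def test_achromatic_image_degenerate(self, params):
        img = np.full((32, 32, 3), 150, dtype=np.uint8)
        with pytest.warns(UserWarning):
            mask = wbc_enhanced_mask(img, 10, params)
        assert not mask.any()

    def test_enhanced_mask_illumination_stable(self, params, simple_scene):
        img, gt = simple_scene
        na = (gt.nucleus_labels > 0).sum()
        m0 = wbc_enhanced_mask(img, na, params)
        m1 = wbc_enhanced_mask(apply_illumination(img, 0.7), na, params)
        assert (m0 ^ m1).sum() <= 0.02 * m0.size


class TestOutsideSeeds:
    def test_union_contains_both_strategies_denoised(self, params, simple_scene):
        img, gt = simple_scene
        na = (gt.nucleus_labels > 0).sum()
        out = build_outside_seeds(img, na, params)
        # no component below the S2 denoising floor survives
        lab = connected_components(out)
        areas = np.bincount(lab.ravel())[1:]
        assert (areas >= params.S2).all()

    def test_every_cell_recalled(self, params):
        spec = SceneSpec(n_wbc=6, n_rbc=25, seed=17)
        img, gt = make_smear(spec)
        na = (gt.nucleus_labels > 0).sum()
        out = build_outside_seeds(img, na, params)
        for i in range(1, gt.n_cells + 1):
            cell = gt.wbc_labels == i
            assert (out & cell).sum() / cell.sum() >= 0.85

    def test_contains_nucleus_seeds(self, params, simple_scene):
        """Hole filling guarantees the outside seeds cover the nuclei."""
        img, gt = simple_scene
        na = (gt.nucleus_labels > 0).sum()
        out = build_outside_seeds(img, na, params)
        nuc = gt.nucleus_labels > 0
        assert (out & nuc).sum() / nuc.sum() >= 0.99
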