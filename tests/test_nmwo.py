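import numpy as np
import pytest

from wbcseg.morphology import RegionProps, connected_components
from wbcseg.nmwo import (
    adaptive_split,
    detect_adhesion,
    marked_watershed,
    postprocess,
    separate_wbcs,
)
from wbcseg.synth import SceneSpec, make_smear


def _props(area, roundness):
    return RegionProps(label=1, area=area, perimeter=0.0, height=1, width=1,
                       roundness=roundness, centroid=(0.0, 0.0))


def _disks(shape, centers, radius):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    mask = np.zeros(shape, bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    return mask


class TestDetectAdhesion:
    @pytest.mark.parametrize("area,roundness,expected", [
        (4000, 3.5, True),
        (3000, 3.5, False),   # area at/below S3
        (4000, 1.5, False),   # roundness at/below R
        (3500, 3.5, False),   # strict inequality on area
    ])
    def test_thresholds(self, params, area, roundness, expected):
        assert detect_adhesion(_props(area, roundness), params) is expected

    def test_comparator_configurable(self, params):
        inverted = params.replace(adhesion_roundness_cmp="lt")
        assert detect_adhesion(_props(4000, 1.5), inverted)
        assert not detect_adhesion(_props(4000, 3.5), inverted)


class TestMarkedWatershed:
    def test_two_disks_split_near_bisector(self):
        mask = _disks((60, 90), [(30, 30), (30, 60)], 20)
        markers = np.zeros(mask.shape, np.int32)
        markers[30, 30] = 1
        markers[30, 60] = 2
        out = marked_watershed(mask, markers)
        assert set(np.unique(out)) == {0, 1, 2}
        # boundary within 2 px of the perpendicular bisector x = 45
        wrong = ((out == 1) & (np.arange(90)[None, :] > 47)) | \
                ((out == 2) & (np.arange(90)[None, :] < 43))
        assert not wrong.any()

    def test_single_marker_keeps_component(self):
        mask = _disks((40, 40), [(20, 20)], 15)
        markers = np.zeros(mask.shape, np.int32)
        markers[20, 20] = 5
        out = marked_watershed(mask, markers)
        np.testing.assert_array_equal(out > 0, mask)

    def test_all_components_marked_no_split(self, rng):
        mask = _disks((80, 80), [(20, 20), (60, 60), (20, 60)], 10)
        markers = connected_components(mask)
        out = marked_watershed(mask, markers)
        np.testing.assert_array_equal(out, markers)

    def test_empty_markers_error(self):
        mask = _disks((30, 30), [(15, 15)], 10)
        with pytest.raises(ValueError):
            marked_watershed(mask, np.zeros_like(mask, dtype=np.int32))

    def test_partitions_mask_exactly(self, rng):
        mask = _disks((60, 60), [(25, 20), (35, 40)], 16)
        markers = np.zeros(mask.shape, np.int32)
        markers[25, 20] = 1
        markers[35, 40] = 2
        out = marked_watershed(mask, markers)
        np.testing.assert_array_equal(out > 0, mask)


class TestAdaptiveSplit:
    def test_dumbbell_splits_via_distance_plateaus(self, params):
        # waist depth < Rs=7 at center distance 20 for radius-12 disks
        region = _disks((40, 60), [(20, 20), (20, 40)], 12)
        out = adaptive_split(region, params)
        assert out.max() == 2
        np.testing.assert_array_equal(out > 0, region)

    def test_convex_disk_not_split(self, params):
        region = _disks((70, 70), [(35, 35)], 30)
        out = adaptive_split(region, params)
        assert out.max() == 1

    def test_vanishing_sliver_returned_unsplit(self, params):
        region = np.zeros((10, 50), bool)
        region[4:6, 5:45] = True  # 2 px thick: erodes away before splitting
        out = adaptive_split(region, params)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, region)


class TestSeparateWbcs:
    def test_overlapping_cells_one_label_per_nucleus(self, params):
        spec = SceneSpec(n_wbc=5, n_rbc=0, overlap_fraction=1.0, seed=12,
                         noise_sd=0)
        img, gt = make_smear(spec)
        out = separate_wbcs(gt.wbc_labels > 0, gt.nucleus_labels, params)
        res = postprocess(out, gt.nucleus_labels > 0)
        assert res.n_cells == gt.n_cells
        for lbl in range(1, res.n_cells + 1):
            nuclei = np.unique(gt.nucleus_labels[res.wbc_labels == lbl])
            assert len(nuclei[nuclei > 0]) == 1

    def test_merged_seed_triggers_second_pass(self, params):
        spec = SceneSpec(n_wbc=2, n_rbc=0, overlap_fraction=1.0, seed=1,
                         noise_sd=0, merged_nuclei=True)
        img, gt = make_smear(spec)
        inside = gt.nucleus_labels > 0
        assert connected_components(inside).max() == 1  # genuinely merged
        out, prov = separate_wbcs(gt.wbc_labels > 0, inside, params,
                                  return_provenance=True)
        res = postprocess(out, inside)
        assert res.n_cells == 2
        assert "split_pass2" in prov.values()

    def test_isolated_cells_early_exit(self, params):
        spec = SceneSpec(n_wbc=4, n_rbc=0, overlap_fraction=0.0, seed=9,
                         noise_sd=0)
        img, gt = make_smear(spec)
        outside = gt.wbc_labels > 0
        out = separate_wbcs(outside, gt.nucleus_labels, params)
        np.testing.assert_array_equal(out, connected_components(outside))

    def test_labels_cover_outside_exactly(self, params):
        spec = SceneSpec(n_wbc=3, n_rbc=0, overlap_fraction=1.0, seed=2,
                         noise_sd=0)
        img, gt = make_smear(spec)
        outside = gt.wbc_labels > 0
        out = separate_wbcs(outside, gt.nucleus_labels, params)
        np.testing.assert_array_equal(out > 0, outside)

    def test_label_count_never_decreases(self, params):
        spec = SceneSpec(n_wbc=4, n_rbc=0, overlap_fraction=1.0, seed=30,
                         noise_sd=0)
        img, gt = make_smear(spec)
        outside = gt.wbc_labels > 0
        before = connected_components(outside).max()
        out = separate_wbcs(outside, gt.nucleus_labels, params)
        assert out.max() >= before


class TestPostprocess:
    def test_nucleus_free_impurity_removed(self):
        wbcs = np.zeros((40, 40), np.int32)
        wbcs[5:15, 5:15] = 1     # real cell
        wbcs[25:30, 25:30] = 2   # debris, no nucleus
        nucleus = np.zeros((40, 40), bool)
        nucleus[8:12, 8:12] = True
        res = postprocess(wbcs, nucleus)
        assert res.n_cells == 1
        assert not (res.wbc_labels == 2).any()

    def test_merged_nucleus_split_by_ridge(self):
        wbcs = np.zeros((30, 60), np.int32)
        wbcs[:, :30] = 1
        wbcs[:, 30:] = 2
        nucleus = np.zeros((30, 60), bool)
        nucleus[12:18, 25:35] = True  # straddles the label boundary
        res = postprocess(wbcs, nucleus)
        labs = np.unique(res.nucleus_labels)
        assert set(labs[labs > 0]) == {1, 2}

    def test_empty_nucleus_empty_result(self):
        wbcs = np.zeros((20, 20), np.int32)
        wbcs[5:15, 5:15] = 1
        res = postprocess(wbcs, np.zeros((20, 20), bool))
        assert res.n_cells == 0

    def test_nucleus_labels_within_wbc_support(self, params):
        spec = SceneSpec(n_wbc=4, n_rbc=5, overlap_fraction=0.5, seed=3,
                         noise_sd=0)
        img, gt = make_smear(spec)
        out = separate_wbcs(gt.wbc_labels > 0, gt.nucleus_labels, params)
        res = postprocess(out, gt.nucleus_labels > 0)
        support = res.nucleus_labels > 0
        np.testing.assert_array_equal(
            res.nucleus_labels[support], res.wbc_labels[support])
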