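import numpy as np
import pytest

from fracseg.io_core import LabelMap
from fracseg.metrics import (
    UndefinedMetricError,
    assd,
    circumscribed_sphere,
    dsc,
    evaluate_case,
    hd95,
    ldsc,
    paired_ttest,
    surface_distances,
)


def exhaustive_surface_distances(pred, gt, spacing):
    """O(n^2) oracle: direct min over all border-voxel pairs."""
    from scipy import ndimage
    sp = np.asarray(spacing)
    struct = ndimage.generate_binary_structure(3, 1)

    def border(m):
        return m & ~ndimage.binary_erosion(m, structure=struct, border_value=0)

    pb = np.argwhere(border(pred)) * sp
    gb = np.argwhere(border(gt)) * sp
    d_pg = np.array([np.sqrt(((gb - p) ** 2).sum(1)).min() for p in pb])
    d_gp = np.array([np.sqrt(((pb - g) ** 2).sum(1)).min() for g in gb])
    return d_pg, d_gp


def random_mask_pair(seed, shape=(10, 10, 10)):
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    a = ndimage.gaussian_filter(rng.normal(size=shape), 1.5) > 0
    b = ndimage.gaussian_filter(rng.normal(size=shape), 1.5) > 0
    if not a.any():
        a[0, 0, 0] = True
    if not b.any():
        b[-1, -1, -1] = True
    return a, b


class TestDsc:
    def test_identical_masks(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:4, 1:4, 1:4] = True
        assert dsc(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert dsc(a, b) == 0.0

    def test_half_overlap_counts(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0:2, 0:2, 0:2] = True        # 8 voxels
        b[1:3, 0:2, 0:2] = True        # 8 voxels, overlap 4
        assert dsc(a, b) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), bool)
        assert dsc(z, z) == 1.0

    def test_symmetry(self):
        a, b = random_mask_pair(3)
        assert dsc(a, b) == dsc(b, a)


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        a = np.zeros((6, 6, 6), bool)
        a[2:5, 2:5, 2:5] = True
        d1, d2 = surface_distances(a, a, (1, 1, 1))
        assert np.all(d1 == 0) and np.all(d2 == 0)

    def test_two_single_voxels(self):
        p = np.zeros((8, 8, 8), bool)
        g = np.zeros((8, 8, 8), bool)
        p[1, 1, 1], g[4, 1, 1] = True, True
        d1, d2 = surface_distances(p, g, (1, 1, 1))
        np.testing.assert_allclose(d1, [3.0])
        np.testing.assert_allclose(d2, [3.0])

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (0.83, 0.83, 0.89)])
    def test_matches_exhaustive_oracle(self, spacing):
        for seed in range(20):
            pred, gt = random_mask_pair(seed)
            d_pg, d_gp = surface_distances(pred, gt, spacing)
            o_pg, o_gp = exhaustive_surface_distances(pred, gt, spacing)
            np.testing.assert_allclose(np.sort(d_pg), np.sort(o_pg), atol=1e-6)
            np.testing.assert_allclose(np.sort(d_gp), np.sort(o_gp), atol=1e-6)


class TestHd95Assd:
    def test_identical_masks_zero(self):
        a = np.zeros((6, 6, 6), bool)
        a[2:4, 2:4, 2:4] = True
        assert hd95(a, a, (1, 1, 1)) == 0.0
        assert assd(a, a, (1, 1, 1)) == 0.0

    def test_oracle_percentile_on_offset_cubes(self):
        for seed in range(20):
            pred, gt = random_mask_pair(seed + 100)
            o_pg, o_gp = exhaustive_surface_distances(pred, gt, (1, 1, 1))
            pooled = np.concatenate([o_pg, o_gp])
            assert hd95(pred, gt, (1, 1, 1)) == pytest.approx(
                np.percentile(pooled, 95), abs=1e-6)
            assert assd(pred, gt, (1, 1, 1)) == pytest.approx(pooled.mean(), abs=1e-6)

    def test_symmetry_when_both_nonempty(self):
        pred, gt = random_mask_pair(7)
        assert hd95(pred, gt, (1, 1, 1)) == pytest.approx(hd95(gt, pred, (1, 1, 1)))
        assert assd(pred, gt, (1, 1, 1)) == pytest.approx(assd(gt, pred, (1, 1, 1)))

    def test_missing_prediction_sphere_conventions(self):
        zz, yy, xx = np.mgrid[:16, :16, :16]
        sphere = ((xx - 8) ** 2 + (yy - 8) ** 2 + (zz - 8) ** 2) <= 25  # r = 5 mm
        empty = np.zeros_like(sphere)
        assert hd95(empty, sphere, (1, 1, 1)) == pytest.approx(10.0, abs=1.0)
        assert assd(empty, sphere, (1, 1, 1)) == pytest.approx(5.0, abs=0.5)

    def test_empty_ground_truth_rejected(self):
        a = np.ones((3, 3, 3), bool)
        with pytest.raises(UndefinedMetricError):
            hd95(a, np.zeros_like(a), (1, 1, 1))


class TestCircumscribedSphere:
    def test_single_voxel_footprint(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        d, r = circumscribed_sphere(m, (1.0, 1.0, 0.89))
        assert d == 1.0 and r == 0.5

    def test_axis_aligned_segment(self):
        m = np.zeros((12, 3, 3), bool)
        m[1:11, 1, 1] = True  # 10 voxels at 1 mm
        d, r = circumscribed_sphere(m, (1, 1, 1))
        assert d == pytest.approx(10.0)

    def test_digitized_sphere(self):
        zz, yy, xx = np.mgrid[:16, :16, :16]
        m = ((xx - 8) ** 2 + (yy - 8) ** 2 + (zz - 8) ** 2) <= 25
        d, r = circumscribed_sphere(m, (1, 1, 1))
        assert d == pytest.approx(10.0, abs=1.0)


class TestLdsc:
    @pytest.fixture
    def split_bone(self):
        frag = np.zeros((20, 8, 8), dtype=np.int32)
        frag[:10] = 1
        frag[10:] = 2
        return LabelMap(frag, spacing=(1, 1, 1), scheme="fragment")

    def test_perfect_prediction_any_band(self, split_bone):
        gt = split_bone.data > 0
        assert ldsc(gt, gt, split_bone, (1, 1, 1), band_mm=2) == 1.0

    def test_errors_outside_band_ignored(self, split_bone):
        gt = split_bone.data > 0
        pred = gt.copy()
        pred[0] = False  # ~9 mm from the CFS
        assert ldsc(pred, gt, split_bone, (1, 1, 1), band_mm=5) == 1.0
        assert dsc(pred, gt) < 1.0

    def test_errors_on_cfs_hurt_more(self, split_bone):
        gt = split_bone.data > 0
        pred = gt.copy()
        pred[9:11] = False
        assert ldsc(pred, gt, split_bone, (1, 1, 1), band_mm=5) < dsc(pred, gt)

    def test_infinite_band_equals_dsc(self, split_bone):
        rng = np.random.default_rng(0)
        gt = split_bone.data > 0
        pred = gt & (rng.random(gt.shape) > 0.2)
        assert ldsc(pred, gt, split_bone, (1, 1, 1), band_mm=1e9) == pytest.approx(
            dsc(pred, gt), abs=1e-9)


class TestEvaluateCase:
    def test_perfect_prediction(self, small_scene):
        from fracseg.pipeline import postprocess_fragments
        gt_inst = {b: postprocess_fragments(f, min_volume_cm3=0.0).data
                   for b, f in small_scene.fragments.items()}
        report = evaluate_case(gt_inst, gt_inst, small_scene.fragments,
                               small_scene.ct.spacing, case_id="perfect")
        assert (report.rows.dsc == 1.0).all()
        assert (report.rows.hd95 == 0.0).all()
        assert not report.rows.missing.any()

    def test_missing_minor_flagged_with_conventions(self, small_scene):
        from fracseg.pipeline import postprocess_fragments
        gt_inst = {b: postprocess_fragments(f, min_volume_cm3=0.0).data
                   for b, f in small_scene.fragments.items()}
        pred = {b: np.where(m == 1, 1, 0) for b, m in gt_inst.items()}  # drop minors
        report = evaluate_case(pred, gt_inst, small_scene.fragments,
                               small_scene.ct.spacing)
        minors = report.rows[report.rows.role == "minor"]
        assert len(minors) >= 1
        assert minors.missing.all()
        for _, row in minors.iterrows():
            gt_mask = gt_inst[row.bone] == row.gt_instance
            d, r = circumscribed_sphere(gt_mask, small_scene.ct.spacing)
            assert row.hd95 == pytest.approx(d)
            assert row.assd == pytest.approx(r)

    def test_aggregates_match_hand_computation(self):
        gt = {1: np.zeros((8, 8, 8), dtype=np.int32)}
        gt[1][1:4] = 1
        gt[1][5:7] = 2
        pred = {1: gt[1].copy()}
        frag = {1: LabelMap(np.where(gt[1] >= 2, 2, gt[1]), spacing=(1, 1, 1),
                            scheme="fragment")}
        report = evaluate_case(pred, gt, frag, (1, 1, 1))
        assert report.aggregates["dsc_mean"] == pytest.approx(report.rows.dsc.mean())
        assert report.aggregates["hd95_median"] == pytest.approx(
            report.rows.hd95.median())


class TestPairedTtest:
    def test_identical_samples(self):
        t, p = paired_ttest([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert t == 0.0 and p == 1.0

    def test_constant_difference_degenerate(self):
        t, p = paired_ttest([2, 3, 4], [1, 2, 3])
        assert np.isinf(t) and p == 0.0

    def test_five_pair_closed_form(self):
        a = np.array([88.0, 90.0, 85.0, 92.0, 80.0])
        b = np.array([85.0, 88.0, 83.0, 90.0, 78.0])
        d = a - b
        expect_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(expect_t, abs=1e-12)
        assert 0 < p < 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
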