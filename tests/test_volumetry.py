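import numpy as np
import pytest

from rapidwashout import phantom
from rapidwashout.pipeline import RunConfig, run_volumes
from rapidwashout.volume import Volume
from rapidwashout.volumetry import (CompartmentMasks, measure, robust_noise_scale,
                                    segment_compartments, segment_perfusion)
from rapidwashout.washoutmap import DifferenceVolume

from conftest import dice


def sphere_diff(value=10.0, radius_vox=5, shape=(24, 24, 24), spacing=(1, 1, 1)):
    ref = Volume(np.zeros(shape), spacing=spacing)
    c = (np.asarray(shape) - 1) / 2
    idx = np.indices(shape)
    inside = sum((idx[a] - c[a]) ** 2 for a in range(3)) <= radius_vox**2
    d = np.where(inside, value, 0.0)
    return DifferenceVolume(d, np.ones(shape, bool), ref), inside


class TestSegmentCompartments:
    def test_constructed_sphere_segmented_exactly(self):
        diff, inside = sphere_diff(value=10.0)
        masks = segment_compartments(diff, threshold=5.0, min_component_mm3=10.0)
        np.testing.assert_array_equal(masks.washout_mask, inside)
        assert not masks.washin_mask.any()

    def test_negation_swaps_compartments_exactly(self):
        diff, inside = sphere_diff(value=10.0)
        masks = segment_compartments(diff.negated(), threshold=5.0,
                                     min_component_mm3=10.0)
        np.testing.assert_array_equal(masks.washin_mask, inside)
        assert not masks.washout_mask.any()

    def test_component_size_filter(self):
        ref = Volume(np.zeros((16, 16, 16)))
        d = np.zeros((16, 16, 16))
        d[2, 2, 2] = 10.0                     # isolated voxel: 1 mm3
        d[8:10, 8:10, 8:12] = 10.0            # 16 mm3 block
        diff = DifferenceVolume(d, np.ones_like(d, bool), ref)
        masks = segment_compartments(diff, threshold=5.0, min_component_mm3=10.0)
        assert masks.washout_mask.sum() == 16
        assert not masks.washout_mask[2, 2, 2]

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        ref = Volume(np.zeros((16, 16, 16)))
        diff = DifferenceVolume(rng.normal(0, 5, (16, 16, 16)),
                                np.ones((16, 16, 16), bool), ref)
        prev_wo = prev_wi = np.inf
        for thr in (2.0, 4.0, 8.0):
            m = segment_compartments(diff, threshold=thr, min_component_mm3=0.0)
            assert m.washout_mask.sum() <= prev_wo
            assert m.washin_mask.sum() <= prev_wi
            prev_wo, prev_wi = m.washout_mask.sum(), m.washin_mask.sum()

    def test_default_threshold_uses_robust_noise_scale(self):
        rng = np.random.default_rng(0)
        ref = Volume(np.zeros((24, 24, 24)))
        diff = DifferenceVolume(rng.normal(0, 4.0, (24, 24, 24)),
                                np.ones((24, 24, 24), bool), ref)
        sigma = robust_noise_scale(diff)
        assert sigma == pytest.approx(4.0, rel=0.15)
        masks = segment_compartments(diff, k=3.0)
        assert masks.threshold == pytest.approx(3.0 * sigma)

    def test_empty_roi_rejected(self):
        diff, _ = sphere_diff()
        with pytest.raises(ValueError):
            segment_compartments(diff, threshold=5.0,
                                 roi=np.zeros(diff.data.shape, bool))

    def test_phantom_compartments_recovered(self, default_case):
        res = run_volumes(default_case.early, default_case.late,
                          config=RunConfig(register_enabled=False))
        assert dice(res.washout_mask, default_case.truth.washout_mask) >= 0.85
        assert dice(res.washin_mask, default_case.truth.washin_mask) >= 0.85


class TestMeasure:
    def test_ratio_formula(self):
        ref_shape = (16, 16, 16)
        wo = np.zeros(ref_shape, bool)
        wi = np.zeros(ref_shape, bool)
        wo.flat[:250] = True
        wi.flat[500:1250] = True
        masks = CompartmentMasks(wo, wi, 5.0, 0.0, (1.0, 1.0, 1.0))
        res = measure(masks)
        assert res.washout_mm3 == 250.0
        assert res.washin_mm3 == 750.0
        assert res.washout_ratio == 0.25

    @pytest.mark.parametrize("wo_n,wi_n,expected", [(100, 0, 1.0), (0, 100, 0.0)])
    def test_ratio_boundaries(self, wo_n, wi_n, expected):
        wo = np.zeros((10, 10, 10), bool)
        wi = np.zeros((10, 10, 10), bool)
        wo.flat[:wo_n] = True
        wi.flat[500:500 + wi_n] = True
        res = measure(CompartmentMasks(wo, wi, 5.0, 0.0, (1.0, 1.0, 1.0)))
        assert res.washout_ratio == expected
        assert res.ratio_defined

    def test_empty_compartments_flag_undefined(self):
        z = np.zeros((4, 4, 4), bool)
        res = measure(CompartmentMasks(z, z, 5.0, 0.0, (1.0, 1.0, 1.0)))
        assert res.washout_mm3 == 0.0 and res.washin_mm3 == 0.0
        assert not res.ratio_defined
        assert np.isnan(res.washout_ratio)

    def test_volume_is_count_times_voxel_volume(self):
        wo = np.zeros((10, 10, 10), bool)
        wo.flat[:100] = True
        wi = np.zeros_like(wo)
        res = measure(CompartmentMasks(wo, wi, 5.0, 0.0, (1.0, 1.0, 2.0)))
        assert res.washout_mm3 == 200.0

    @pytest.mark.parametrize("s", [0.5, 2.0, 3.0])
    def test_volume_scales_cubically_with_spacing(self, s):
        wo = np.zeros((8, 8, 8), bool)
        wo[2:5, 2:5, 2:5] = True
        wi = np.zeros_like(wo)
        base = measure(CompartmentMasks(wo, wi, 5.0, 0.0, (1.0, 1.0, 1.0)))
        scaled = measure(CompartmentMasks(wo, wi, 5.0, 0.0, (s, s, s)))
        assert scaled.washout_mm3 == base.washout_mm3 * s**3

    def test_per_lesion_table(self):
        wo = np.zeros((20, 20, 20), bool)
        wo[2:5, 2:5, 2:5] = True
        wo[12:16, 12:16, 12:16] = True
        wi = np.zeros_like(wo)
        res = measure(CompartmentMasks(wo, wi, 5.0, 0.0, (1.0, 1.0, 1.0)))
        assert res.lesion_count == 2
        assert sorted(res.lesions.volume_mm3) == [27.0, 64.0]

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError):
            CompartmentMasks(m, m, 5.0, 0.0, (1.0, 1.0, 1.0))


class TestSegmentPerfusion:
    def test_uniform_below_threshold_empty(self):
        rcbv = Volume(np.full((10, 10, 10), 1.0))
        res = segment_perfusion(rcbv)
        assert not res.mask.any()
        assert res.volume_mm3 == 0.0
        assert np.isnan(res.max_rcbv)

    def test_slab_above_threshold_measured(self):
        # 10x10 mm in-plane (1 cm2 cross-section), 6 slices -> 600 voxels
        data = np.full((20, 20, 8), 1.0)
        data[5:15, 5:15, 1:7] = 2.0
        rcbv = Volume(data, spacing=(1.0, 1.0, 1.0))
        res = segment_perfusion(rcbv, rcbv_threshold=1.2, min_area_cm2=0.25)
        assert res.volume_mm3 == 600.0
        assert res.max_rcbv == 2.0

    def test_small_cross_section_removed(self):
        # 0.1 cm2 cross-section slab: below the 0.25 cm2 area criterion
        data = np.full((20, 20, 8), 1.0)
        data[5:10, 5:7, 1:7] = 2.0  # 5x2 mm = 0.1 cm2
        rcbv = Volume(data, spacing=(1.0, 1.0, 1.0))
        res = segment_perfusion(rcbv, rcbv_threshold=1.2, min_area_cm2=0.25)
        assert res.volume_mm3 == 0.0

    def test_enhancement_mask_restricts(self):
        data = np.full((20, 20, 8), 2.0)
        rcbv = Volume(data, spacing=(1.0, 1.0, 1.0))
        enh = np.zeros(data.shape, bool)
        enh[5:15, 5:15, :] = True
        res = segment_perfusion(rcbv, enhancement_mask=enh)
        assert res.volume_mm3 == enh.sum() * 1.0

    def test_phantom_rcbv_marks_tumor_filters_thin_vessel(self, default_case):
        res = segment_perfusion(default_case.rcbv)
        labels = default_case.truth.labels
        # tumor (bulky) survives the area criterion
        assert dice(res.mask, labels == phantom.TUMOR) >= 0.9
        # the 2.5 mm vessel has a 0.2 cm2 cross-section: removed by the
        # 0.25 cm2 in-plane area filter
        assert not (res.mask & (labels == phantom.VESSEL)).any()
        assert res.max_rcbv > 1.2
        # with the area filter disabled the vessel is hyperperfused
        res_all = segment_perfusion(default_case.rcbv, min_area_cm2=0.0)
        assert (res_all.mask & (labels == phantom.VESSEL)).sum() > 0
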