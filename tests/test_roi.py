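import numpy as np
import pytest
from skimage.draw import disk

from dwifilters import (
    LesionROI,
    dilate_lesion_roi,
    dilate_roi,
    map_annotation_to_native,
    roi_mean_adc,
    select_index_slice,
)


def brute_force_dilate(mask):
    """Any pixel with an 8-neighborhood intersecting the mask."""
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    for i in range(rows):
        for j in range(cols):
            lo_i, hi_i = max(i - 1, 0), min(i + 2, rows)
            lo_j, hi_j = max(j - 1, 0), min(j + 2, cols)
            out[i, j] = mask[lo_i:hi_i, lo_j:hi_j].any()
    return out


class TestDilation:
    def test_single_pixel_becomes_3x3_block(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        out = dilate_roi(mask)
        assert out.sum() == 9
        assert out[2:5, 2:5].all()

    def test_border_clipping_no_wraparound(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        out = dilate_roi(mask)
        assert out.sum() == 4
        assert not out[-1].any() and not out[:, -1].any()

    def test_matches_neighborhood_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((12, 15)) < 0.2
            if not mask.any():
                mask[4, 4] = True
            np.testing.assert_array_equal(dilate_roi(mask), brute_force_dilate(mask))

    def test_strictly_increases_pixel_count(self, rng):
        mask = rng.random((10, 10)) < 0.3
        mask[5, 5] = True
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
        assert dilate_roi(mask).sum() > mask.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dilate_roi(np.zeros((4, 4), bool))


class TestIndexSlice:
    def test_single_slice(self):
        roi = LesionROI(masks={5: np.ones((3, 3), bool)}, pixel_area=1.0)
        assert select_index_slice(roi) == 5

    def test_argmax_of_area(self, small_roi):
        assert select_index_slice(small_roi) == 3

    def test_tie_broken_to_lowest_slice(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        roi = LesionROI(masks={6: m.copy(), 4: m.copy()}, pixel_area=1.0)
        assert select_index_slice(roi) == 4

    def test_permutation_stable(self, small_roi):
        reordered = LesionROI(
            masks={k: small_roi.masks[k] for k in [4, 2, 3]},
            pixel_area=small_roi.pixel_area,
        )
        assert select_index_slice(reordered) == select_index_slice(small_roi)


class TestAnnotationMapping:
    def test_identity_at_native_resolution(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 3:6] = True
        out = map_annotation_to_native(mask, (8, 8), 1.5625)
        np.testing.assert_array_equal(out, mask)

    def test_exact_integer_downscale_preserves_area(self):
        # a 4x4 block annotated on a 2x-upsampled grid of a 10x10 native image
        ann = np.zeros((20, 20), bool)
        ann[8:12, 8:12] = True
        native_pixel_area = 1.25**2
        out = map_annotation_to_native(ann, (10, 10), native_pixel_area)
        assert out.sum() == 4  # 2x2 native block
        ann_area = ann.sum() * native_pixel_area * (10 * 10) / (20 * 20)
        assert out.sum() * native_pixel_area == pytest.approx(ann_area)

    @pytest.mark.parametrize("radius,center", [(6.0, (19.3, 22.8)), (9.5, (20.6, 21.2)), (13.0, (21.4, 20.7))])
    def test_convex_blob_area_within_one_native_pixel(self, radius, center):
        """Physical-area bookkeeping at 1.4x scaling, off-grid convex blobs."""
        native_shape = (30, 30)
        ann_shape = (42, 42)
        ann = np.zeros(ann_shape, bool)
        rr, cc = disk(center, radius, shape=ann_shape)
        ann[rr, cc] = True
        native_pixel_area = 1.25**2
        ann_pixel_area = native_pixel_area * (30 * 30) / (42 * 42)
        out = map_annotation_to_native(ann, native_shape, native_pixel_area)
        err = abs(out.sum() * native_pixel_area - ann.sum() * ann_pixel_area)
        assert err <= native_pixel_area

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            map_annotation_to_native(np.zeros((10, 10), bool), (5, 5), 1.0)


class TestRoiMeanADC:
    def test_constant_field(self, small_roi):
        grid = np.full((6, 12, 12), 1.3e-3)
        assert roi_mean_adc(grid, small_roi) == pytest.approx(1.3e-3)

    def test_two_pixel_arithmetic(self):
        grid = np.zeros((1, 4, 4))
        grid[0, 1, 1] = 1.0e-3
        grid[0, 1, 2] = 2.0e-3
        mask = np.zeros((4, 4), bool)
        mask[1, 1:3] = True
        roi = LesionROI(masks={0: mask}, pixel_area=1.0, dilated=True)
        assert roi_mean_adc(grid, roi) == pytest.approx(1.5e-3)

    def test_phantom_ground_truth_recovery(self, noisefree_mass_phantom):
        """Noise-free phantom: designed mean ADC recovered within 1%."""
        from dwifilters import compute_adc_maps

        ph, spec, lesion = noisefree_mass_phantom
        maps = compute_adc_maps(ph.study)
        measured = roi_mean_adc(maps.adc_mean, ph.rois["mass0"])
        assert measured == pytest.approx(lesion.mean_adc_target, rel=0.01)

    def test_dilation_state_respected(self, small_roi):
        grid = np.full((6, 12, 12), 2.0e-3)
        dilated = dilate_lesion_roi(small_roi)
        assert dilated.dilated
        # constant field: mean identical whichever mask is used
        assert roi_mean_adc(grid, dilated) == pytest.approx(2.0e-3)
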