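"""Segmentation, ray casting, bounding boxes and normalisation."""

import numpy as np
import pytest

from rms.phantom import PhantomSpec, synth_volume_4d
from rms.preprocess import (
    ProjectionGeometry,
    crop_and_normalize,
    hu_to_attenuation,
    lung_bounding_box,
    preprocess_case,
    ray_cast_drr,
    resize_bilinear,
    segment_lungs,
)


@pytest.fixture(scope="module")
def volume_case():
    spec = PhantomSpec()
    vols, masks = synth_volume_4d(spec, 2)
    return spec, vols, masks


class TestSegmentLungs:
    def test_recovers_phantom_labels(self, volume_case):
        _, vols, masks = volume_case
        seg = segment_lungs(vols[0], -400.0)
        inter = np.logical_and(seg > 0, masks[0] > 0).sum()
        union = np.logical_or(seg > 0, masks[0] > 0).sum()
        assert inter / union >= 0.99
        overlap = masks[0] > 0
        assert np.mean(seg[overlap] == masks[0][overlap]) >= 0.99

    def test_uniform_soft_tissue_has_no_lung(self):
        with pytest.raises(ValueError):
            segment_lungs(np.zeros((32, 32, 32)), -400.0)

    def test_extreme_threshold_empties_mask(self, volume_case):
        _, vols, _ = volume_case
        with pytest.raises(ValueError):
            segment_lungs(vols[0], -2000.0)

    def test_rejects_non_finite(self):
        vol = np.zeros((32, 32, 32))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            segment_lungs(vol)


class TestRayCast:
    def test_uniform_slab_integral_is_exact(self):
        vol = np.full((8, 8, 8), -1000.0)
        vol[:, :, 2:5] = 0.0  # water slab, attenuation 1, 3 voxels thick
        mask = np.zeros_like(vol)
        mask[:, :, 2:5] = 1
        drr = ray_cast_drr(vol, mask, ProjectionGeometry(step_mm=1.0))
        assert np.allclose(drr, 3.0)

    def test_matches_per_ray_summation_oracle(self, volume_case):
        _, vols, masks = volume_case
        geom = ProjectionGeometry()
        drr = ray_cast_drr(vols[0], masks[0], geom)
        atten = hu_to_attenuation(vols[0]) * (masks[0] > 0)
        h, w, _ = atten.shape
        oracle = np.zeros((h, w))
        for i in range(h):
            for j in range(w):
                oracle[i, j] = atten[i, j, :].sum()
        assert np.abs(drr - oracle).max() <= 1e-6

    def test_zero_attenuation_projects_to_zero(self):
        vol = np.full((8, 8, 8), -1000.0)
        drr = ray_cast_drr(vol, np.ones_like(vol), ProjectionGeometry())
        assert np.all(drr == 0.0)

    def test_linear_in_the_volume(self, rng):
        v1 = rng.random((8, 8, 8)) * 1000 - 1000
        v2 = rng.random((8, 8, 8)) * 1000 - 1000
        mask = np.ones_like(v1)
        geom = ProjectionGeometry()
        a1 = hu_to_attenuation(v1)
        a2 = hu_to_attenuation(v2)
        # linearity holds on the attenuation maps (post HU clamping)
        lhs = (a1 + a2).sum(axis=2)
        rhs = a1.sum(axis=2) + a2.sum(axis=2)
        assert np.abs(lhs - rhs).max() <= 1e-6
        assert np.abs(ray_cast_drr(v1, mask, geom) - a1.sum(axis=2)).max() <= 1e-6

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(step_mm=0.0)
        with pytest.raises(ValueError):
            ProjectionGeometry(mode="perspective")  # needs source distance


class TestBoundingBox:
    def test_single_pixel(self):
        m = np.zeros((10, 12), dtype=np.uint8)
        m[5, 7] = 1
        assert lung_bounding_box(m[None], 0) == (5, 7, 6, 8)

    def test_union_over_phases(self):
        m1 = np.zeros((40, 20), dtype=np.uint8)
        m2 = np.zeros((40, 20), dtype=np.uint8)
        m1[10:21, 5:10] = 1
        m2[15:31, 5:10] = 1
        assert lung_bounding_box(np.stack([m1, m2]), 0) == (10, 5, 31, 10)

    def test_margin_clips_to_frame(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[0:2, 8:10] = 1
        assert lung_bounding_box(m[None], 2) == (0, 6, 4, 10)

    def test_monotone_under_mask_growth(self, rng):
        m = (rng.random((20, 20)) > 0.8).astype(np.uint8)
        m[10, 10] = 1
        b1 = lung_bounding_box(m[None], 0)
        m2 = m.copy()
        m2[0, 0] = 1
        b2 = lung_bounding_box(m2[None], 0)
        assert b2[0] <= b1[0] and b2[1] <= b1[1] and b2[2] >= b1[2] and b2[3] >= b1[3]

    def test_empty_union_raises(self):
        with pytest.raises(ValueError):
            lung_bounding_box(np.zeros((2, 8, 8), dtype=np.uint8), 0)


class TestCropAndNormalize:
    def test_full_frame_rescale_preserves_argmax(self, rng):
        img = rng.random((16, 16)) * 50 + 10
        out = crop_and_normalize(img, (0, 0, 16, 16), (16, 16))
        assert out.min() == 0.0 and out.max() == pytest.approx(1.0)
        assert np.unravel_index(out.argmax(), out.shape) == \
            np.unravel_index(img.argmax(), img.shape)

    def test_constant_image_maps_to_zeros(self):
        out = crop_and_normalize(np.full((8, 8), 4.2), (0, 0, 8, 8), (8, 8))
        assert np.all(out == 0.0)

    def test_downscale_matches_bilinear_oracle(self):
        img = np.indices((8, 8)).sum(axis=0) % 2.0  # checkerboard
        out = resize_bilinear(img, (4, 4))
        h, w, oh, ow = 8, 8, 4, 4
        oracle = np.zeros((oh, ow))
        for i in range(oh):
            for j in range(ow):
                r = i * (h - 1) / (oh - 1)
                c = j * (w - 1) / (ow - 1)
                r0, c0 = min(int(r), h - 2), min(int(c), w - 2)
                ar, ac = r - r0, c - c0
                oracle[i, j] = ((1 - ar) * (1 - ac) * img[r0, c0]
                                + (1 - ar) * ac * img[r0, c0 + 1]
                                + ar * (1 - ac) * img[r0 + 1, c0]
                                + ar * ac * img[r0 + 1, c0 + 1])
        assert np.abs(out - oracle).max() <= 1e-6

    def test_degenerate_bbox_raises(self, rng):
        with pytest.raises(ValueError):
            crop_and_normalize(rng.random((8, 8)), (3, 3, 3, 6), (4, 4))


class TestPreprocessCase:
    def test_end_to_end_invariants(self, volume_case):
        spec, vols, _ = volume_case
        seq = preprocess_case(list(vols), out_size=(64, 64),
                              voxel_spacing_mm=spec.pixel_spacing_mm)
        assert seq.phases.shape == (10, 64, 64)
        assert seq.phases.min() >= 0.0 and seq.phases.max() <= 1.0
        assert seq.lung_masks.shape == seq.phases.shape
        assert seq.spacing_mm > 0
        r0, c0, r1, c1 = seq.bbox
        assert 0 <= r0 < r1 and 0 <= c0 < c1
        # exhalation shrinks the projected lung
        assert (seq.lung_masks[5] > 0).sum() < (seq.lung_masks[0] > 0).sum()

    def test_caller_owns_phase_order(self, volume_case):
        spec, vols, _ = volume_case
        order = [0, 5, 1, 6, 2, 7, 3, 8, 4, 9]
        seq = preprocess_case([vols[i] for i in order], out_size=(32, 32),
                              voxel_spacing_mm=spec.pixel_spacing_mm)
        ref = preprocess_case(list(vols), out_size=(32, 32),
                              voxel_spacing_mm=spec.pixel_spacing_mm)
        assert np.allclose(seq.phases[1], ref.phases[5], atol=1e-6)

    def test_requires_ten_phases(self, volume_case):
        _, vols, _ = volume_case
        with pytest.raises(ValueError):
            preprocess_case(list(vols[:9]))
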