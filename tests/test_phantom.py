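"""Synthetic phantom generator: determinism, anatomy, cycle structure."""

import dataclasses
import json

import numpy as np
import pytest
from scipy import ndimage

from rms.evaluate import dice_score, diaphragm_length
from rms.model import spatial_transform
from rms.phantom import (
    LEFT,
    RIGHT,
    PhantomSpec,
    build_phantom_dataset,
    load_manifest,
    phase_weight,
    render_phantom_sequence,
    synth_anatomy_2d,
    synth_cycle_dvfs,
    synth_volume_4d,
)


class TestAnatomy:
    def test_deterministic_per_seed(self, default_spec):
        a1, m1, _ = synth_anatomy_2d(default_spec, 42)
        a2, m2, _ = synth_anatomy_2d(default_spec, 42)
        assert np.array_equal(a1, a2) and np.array_equal(m1, m2)
        a3, _, _ = synth_anatomy_2d(default_spec, 43)
        assert not np.array_equal(a1, a3)

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_two_lungs_left_of_right(self, default_spec, seed):
        img, mask, _ = synth_anatomy_2d(default_spec, seed)
        lab, n = ndimage.label(mask > 0)
        assert n == 2
        c_left = ndimage.center_of_mass(mask == LEFT)
        c_right = ndimage.center_of_mass(mask == RIGHT)
        assert c_left[1] < c_right[1]
        assert img.min() >= 0.0 and img.max() <= 1.0
        # lungs darker than the surrounding body
        assert img[mask > 0].mean() < img[mask == 0].mean()

    def test_nodules_differ_on_disc_shaped_supports(self, default_spec):
        plain, _, _ = synth_anatomy_2d(default_spec, 5)
        spec2 = dataclasses.replace(default_spec, nodule_count=2)
        with_nod, _, _ = synth_anatomy_2d(spec2, 5)
        diff = np.abs(with_nod.astype(float) - plain.astype(float)) > 1e-6
        lab, n = ndimage.label(diff)
        assert n == 2
        for i in range(1, n + 1):
            comp = lab == i
            area = comp.sum()
            rows = np.flatnonzero(comp.any(axis=1))
            cols = np.flatnonzero(comp.any(axis=0))
            extent = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
            assert area >= 0.5 * np.pi * (extent / 2.0) ** 2  # compact/disc-like

    def test_rejects_tiny_frame(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_size=(16, 16))


class TestCycleDvfs:
    def test_zero_amplitude_zero_fields(self, default_spec):
        spec = dataclasses.replace(default_spec, diaphragm_amplitude_mm=0.0)
        _, _, params = synth_anatomy_2d(spec, 3)
        dvfs = synth_cycle_dvfs(spec, params, 3)
        assert np.all(dvfs == 0)

    def test_peak_vertical_displacement_tracks_phase_weight(self, default_spec):
        spec = dataclasses.replace(default_spec, amplitude_jitter=0.0)
        _, _, params = synth_anatomy_2d(spec, 4)
        dvfs = synth_cycle_dvfs(spec, params, 4)
        peak5 = np.abs(dvfs[4, 1]).max()          # phase t=5
        expected = (spec.diaphragm_amplitude_mm / spec.pixel_spacing_mm
                    * params["height_factor"] ** 1.5 * phase_weight(5))
        assert peak5 == pytest.approx(expected, rel=0.05)
        # all phases scale as sin^2(pi t / 10)
        peaks = np.abs(dvfs[:, 1]).reshape(9, -1).max(axis=1)
        ratio = peaks / phase_weight(np.arange(1, 10))
        assert np.allclose(ratio, ratio[0], rtol=1e-5)

    def test_cycle_returns_toward_inhale(self):
        w = phase_weight(np.arange(10))
        assert w[1] < w[4] and w[9] < w[5] and w[0] == 0.0

    def test_apex_moves_less_than_base(self, default_spec):
        _, _, params = synth_anatomy_2d(default_spec, 2)
        dvfs = synth_cycle_dvfs(default_spec, params, 2)
        u5 = np.abs(dvfs[4, 1])
        apex_row = int(params["apex_row"])
        dome_row = int(params["dome_row"])
        assert u5[apex_row].max() < 0.5 * u5[dome_row].max()


class TestSequence:
    @pytest.mark.parametrize("seed", range(10))
    def test_warp_consistency(self, default_spec, seed):
        """Warping p0 by the stored field reproduces every phase image."""
        case = render_phantom_sequence(default_spec, seed)
        for t in range(1, 10):
            warped = spatial_transform(case.images[0], case.gt_dvfs[t - 1])
            assert np.abs(warped - case.images[t]).max() <= 0.02

    def test_zero_amplitude_identity_sequence(self, default_spec):
        spec = dataclasses.replace(default_spec, diaphragm_amplitude_mm=0.0,
                                   noise_sigma=0.0)
        case = render_phantom_sequence(spec, 3)
        for t in range(1, 10):
            assert np.array_equal(case.images[0], case.images[t])
            assert dice_score(case.mask_binary(0), case.mask_binary(t)) == 1.0

    def test_default_difficulty_band(self, default_spec):
        """Default amplitude produces non-trivial mid-cycle motion."""
        d5 = []
        for seed in range(20):
            case = render_phantom_sequence(default_spec, seed)
            d5.append(dice_score(case.mask_binary(0), case.mask_binary(5)))
        assert 0.85 <= float(np.mean(d5)) <= 0.95

    def test_diaphragm_dome_rises_at_end_exhale(self, default_case):
        spacing = default_case.spacing_mm
        for lab in (LEFT, RIGHT):
            len0 = diaphragm_length(default_case.lung_masks[0] == lab, spacing)
            len5 = diaphragm_length(default_case.lung_masks[5] == lab, spacing)
            assert len5 < len0  # dome strictly superior at end-exhale

    def test_masks_keep_two_components(self, default_case):
        for t in range(10):
            lab, n = ndimage.label(default_case.lung_masks[t] > 0)
            assert n == 2


class TestVolume4D:
    def test_lung_hu_range_and_exhale_shrink(self, default_spec):
        vols, masks = synth_volume_4d(default_spec, 1)
        assert vols.shape[0] == 10 and masks.shape == vols.shape
        lung_vals = vols[masks > 0]
        assert lung_vals.min() > -950 and lung_vals.max() < -650
        assert (masks[5] > 0).sum() < (masks[0] > 0).sum()

    def test_zero_amplitude_static_volume(self, default_spec):
        spec = dataclasses.replace(default_spec, diaphragm_amplitude_mm=0.0)
        vols, masks = synth_volume_4d(spec, 1)
        assert np.array_equal(vols[0], vols[5])
        assert np.array_equal(masks[0], masks[9])

    def test_rejects_small_volume(self, default_spec):
        spec = dataclasses.replace(default_spec, volume_size=(16, 48, 32))
        with pytest.raises(ValueError):
            synth_volume_4d(spec, 0)


class TestDataset:
    def test_small_dataset_disjoint_seeds(self, tmp_path, small_spec):
        manifest = build_phantom_dataset(tmp_path / "ds", 2, 1, spec=small_spec, seed=5)
        assert len(manifest["cases"]) == 3
        seeds = [c["seed"] for c in manifest["cases"]]
        assert len(set(seeds)) == 3
        splits = [c["split"] for c in manifest["cases"]]
        assert splits == ["train", "train", "test"]

    def test_rebuild_reproduces_manifest_byte_identical(self, tmp_path, small_spec):
        build_phantom_dataset(tmp_path / "a", 2, 1, spec=small_spec, seed=5)
        build_phantom_dataset(tmp_path / "b", 2, 1, spec=small_spec, seed=5)
        ma = (tmp_path / "a" / "manifest.json").read_bytes()
        mb = (tmp_path / "b" / "manifest.json").read_bytes()
        assert ma == mb

    def test_refuses_overwrite_unless_forced(self, tmp_path, small_spec):
        build_phantom_dataset(tmp_path / "ds", 1, 1, spec=small_spec, seed=0)
        with pytest.raises(FileExistsError):
            build_phantom_dataset(tmp_path / "ds", 1, 1, spec=small_spec, seed=0)
        build_phantom_dataset(tmp_path / "ds", 1, 1, spec=small_spec, seed=0,
                              force=True)

    def test_default_split_is_40_20(self):
        import inspect

        sig = inspect.signature(build_phantom_dataset)
        assert sig.parameters["n_train"].default == 40
        assert sig.parameters["n_test"].default == 20

    def test_3d_mode_writes_volumes(self, tmp_path, default_spec):
        build_phantom_dataset(tmp_path / "ds3", 1, 1, spec=default_spec, seed=2,
                              mode="3d")
        manifest = load_manifest(tmp_path / "ds3")
        assert manifest["mode"] == "3d"
        with np.load(tmp_path / "ds3" / manifest["cases"][0]["file"]) as z:
            assert z["volumes"].shape[0] == 10
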