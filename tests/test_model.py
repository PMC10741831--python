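"""Network contracts and the spatial transformer against a brute-force oracle."""

import numpy as np
import pytest

import rms._autodiff as ad
from rms._autodiff import Tensor
from rms.model import MotionNet, RMSCheckpoint, spatial_transform, warp_labeled_mask


def brute_force_bilinear_warp(image, dvf):
    """Direct per-pixel implementation of the sampling equation."""
    h, w = image.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            r = min(max(i + dvf[1, i, j], 0.0), h - 1.0)
            c = min(max(j + dvf[0, i, j], 0.0), w - 1.0)
            r0 = min(int(np.floor(r)), h - 2)
            c0 = min(int(np.floor(c)), w - 2)
            ar, ac = r - r0, c - c0
            out[i, j] = ((1 - ar) * (1 - ac) * image[r0, c0]
                         + (1 - ar) * ac * image[r0, c0 + 1]
                         + ar * (1 - ac) * image[r0 + 1, c0]
                         + ar * ac * image[r0 + 1, c0 + 1])
    return out


class TestSpatialTransform:
    def test_zero_field_is_identity(self, rng):
        img = rng.random((12, 12))
        out = spatial_transform(img, np.zeros((2, 12, 12)))
        assert np.array_equal(out, img)

    def test_integer_shift_with_border_clamp(self, rng):
        img = rng.random((8, 8))
        dvf = np.zeros((2, 8, 8))
        dvf[0] = 3.0  # sample 3 columns to the right -> content shifts left
        out = spatial_transform(img, dvf)
        assert np.allclose(out[:, :5], img[:, 3:])
        assert np.allclose(out[:, 5:], img[:, [7]])  # clamped at the border

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16))
        dvf = rng.normal(0, 1.5, size=(2, 16, 16))
        expected = brute_force_bilinear_warp(img, dvf)
        assert np.abs(spatial_transform(img, dvf) - expected).max() < 1e-5
        # autodiff twin agrees with the numpy path
        out_t = ad.grid_sample_bilinear(
            Tensor(img[None, None]), Tensor(dvf[None].astype(np.float32)))
        assert np.abs(out_t.data[0, 0] - expected).max() < 1e-4

    def test_linear_in_the_image_argument(self, rng):
        i1, i2 = rng.random((10, 10)), rng.random((10, 10))
        dvf = rng.normal(0, 1, size=(2, 10, 10))
        lhs = spatial_transform(2.0 * i1 + 3.0 * i2, dvf)
        rhs = 2.0 * spatial_transform(i1, dvf) + 3.0 * spatial_transform(i2, dvf)
        assert np.abs(lhs - rhs).max() < 1e-6

    def test_nearest_mode_preserves_labels(self, rng):
        mask = (rng.random((10, 10)) > 0.5).astype(np.uint8) * 2
        dvf = rng.normal(0, 1, size=(2, 10, 10))
        out = warp_labeled_mask(mask, dvf)
        assert set(np.unique(out)) <= {0, 2}

    def test_rejects_non_finite_field(self, rng):
        dvf = np.zeros((2, 8, 8))
        dvf[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            spatial_transform(rng.random((8, 8)), dvf)


class TestEncoderDecoder:
    def test_encoder_shapes_and_latent_length(self):
        net = MotionNet(image_size=64, base_channels=16, seed=0)
        x0, skips = net.encode(np.random.default_rng(0).random((64, 64)))
        assert x0.shape == (512,)
        assert [s.shape[-1] for s in skips] == [64, 32, 16, 8]
        assert [s.shape[0] for s in skips] == [16, 32, 64, 128]

    def test_rejects_bad_input_size(self):
        with pytest.raises(ValueError):
            MotionNet(image_size=50)
        net = MotionNet(image_size=32)
        with pytest.raises(ValueError):
            net.forward(np.zeros((50, 50), dtype=np.float32))

    def test_rollout_produces_nine_reproducible_latents(self, rng):
        net = MotionNet(image_size=32, seed=3)
        x0 = rng.normal(size=512).astype(np.float32)
        xs1 = net.rollout_latents(x0)
        xs2 = net.rollout_latents(x0)
        assert len(xs1) == 9
        for a, b in zip(xs1, xs2):
            assert np.array_equal(a, b)

    def test_decoder_shape_and_zero_head(self, rng):
        net = MotionNet(image_size=32, seed=1)
        _, skips = net.encode(rng.random((32, 32)))
        dvf = net.decode_dvf(rng.normal(size=512), skips)
        assert dvf.shape == (2, 32, 32)
        assert np.all(dvf == 0)  # freshly initialised head outputs zero fields

    def test_decoder_is_differentiable_wrt_latent(self, rng):
        net = MotionNet(image_size=32, seed=1)
        # non-zero head so the output actually depends on the latent
        net.head.w.data = rng.normal(0, 0.1, size=net.head.w.data.shape).astype(
            np.float32)
        p0 = Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
        x0, skips = net.encode_batch(p0)
        lat = Tensor(rng.normal(size=(1, 512)).astype(np.float32),
                     requires_grad=True)
        out = net.decode_batch(lat, skips)
        ad.tsum(ad.square(out)).backward()
        assert lat.grad is not None and np.abs(lat.grad).max() > 0


class TestForward:
    def test_forward_contract_and_zero_head_identity(self, rng):
        net = MotionNet(image_size=32, seed=0)
        p0 = rng.random((32, 32)).astype(np.float32)
        dvfs, preds = net.forward(p0)
        assert dvfs.shape == (9, 2, 32, 32) and preds.shape == (9, 32, 32)
        # zero-initialised head -> zero fields -> every prediction equals p0
        assert np.all(dvfs == 0)
        assert np.allclose(preds, p0, atol=1e-6)

    def test_forward_deterministic(self, rng):
        net = MotionNet(image_size=32, seed=0)
        for p in net.parameters().values():  # random weights, not just init
            p.data += rng.normal(0, 0.01, size=p.data.shape).astype(np.float32)
        p0 = rng.random((32, 32)).astype(np.float32)
        d1, i1 = net.forward(p0)
        d2, i2 = net.forward(p0)
        assert np.array_equal(d1, d2) and np.array_equal(i1, i2)

    def test_displacements_bounded_by_max_disp(self, rng):
        net = MotionNet(image_size=32, max_disp=5.0, seed=0)
        for p in net.parameters().values():
            p.data += rng.normal(0, 0.5, size=p.data.shape).astype(np.float32)
        dvfs, _ = net.forward(rng.random((32, 32)).astype(np.float32))
        assert np.abs(dvfs).max() <= 5.0


class TestCheckpoint:
    def test_roundtrip_bit_identical_predictions(self, tmp_path, rng):
        net = MotionNet(image_size=32, seed=2)
        for p in net.parameters().values():
            p.data += rng.normal(0, 0.05, size=p.data.shape).astype(np.float32)
        p0 = rng.random((32, 32)).astype(np.float32)
        d1, i1 = net.forward(p0)
        ck = RMSCheckpoint(arch=net.arch_dict(), params=net.state_dict(), seed=2)
        ck.save(tmp_path / "ck.npz")
        net2 = RMSCheckpoint.load(tmp_path / "ck.npz").build_net()
        d2, i2 = net2.forward(p0)
        assert np.array_equal(d1, d2) and np.array_equal(i1, i2)

    def test_save_load_idempotent(self, tmp_path):
        net = MotionNet(image_size=32, seed=2)
        ck = RMSCheckpoint(arch=net.arch_dict(), params=net.state_dict(), seed=2)
        ck.save(tmp_path / "a.npz")
        ck2 = RMSCheckpoint.load(tmp_path / "a.npz")
        ck2.save(tmp_path / "b.npz")
        ck3 = RMSCheckpoint.load(tmp_path / "b.npz")
        assert ck2.arch_hash == ck3.arch_hash
        for k in ck2.params:
            assert np.array_equal(ck2.params[k], ck3.params[k])
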