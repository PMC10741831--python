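"""Radiograph motion simulation network.

A U-Net-style encoder compresses the end-of-inhale (EOI) projection ``p0``
into a 1x512 latent vector, a two-layer one-to-many LSTM rolls the latent
forward through the nine remaining phases of the breathing cycle, and a
decoder with skip connections emits one two-channel displacement vector
field (DVF) per phase. A differentiable bilinear spatial transformer warps
``p0`` by each DVF to produce the predicted phase images, so anatomy is
deformed rather than hallucinated.

Displacement convention: fields are backward-warping and in pixel units —
``out(i, j) = p0(i + u_y(i, j), j + u_x(i, j))`` with channel 0 holding
``u_x`` (columns) and channel 1 ``u_y`` (rows).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Conv3, Linear, LSTMCell

__all__ = [
    "MotionNet",
    "RMSCheckpoint",
    "spatial_transform",
    "warp_labeled_mask",
]

LATENT_DIM_DEFAULT = 512
N_STEPS_DEFAULT = 9


# ---------------------------------------------------------------------------
# spatial transformer (numpy forward path; training uses the autodiff twin)
# ---------------------------------------------------------------------------

def spatial_transform(image: np.ndarray, dvf: np.ndarray, interp: str = "bilinear") -> np.ndarray:
    """Backward-warp a single 2D image by a displacement field.

    Each output pixel ``(i, j)`` samples the input at
    ``(i + dvf[1, i, j], j + dvf[0, i, j])``; out-of-bounds coordinates clamp
    to the border. ``interp`` is ``"bilinear"`` (images) or ``"nearest"``
    (binary or labeled masks, output stays label-valued).
    """
    image = np.asarray(image)
    dvf = np.asarray(dvf, dtype=np.float64)
    if image.ndim != 2 or dvf.shape != (2,) + image.shape:
        raise ValueError(f"incongruent shapes image {image.shape}, dvf {dvf.shape}")
    if not np.all(np.isfinite(dvf)):
        raise ValueError("displacement field contains non-finite values")
    h, w = image.shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    rows = np.clip(ii + dvf[1], 0.0, h - 1.0)
    cols = np.clip(jj + dvf[0], 0.0, w - 1.0)
    if interp == "nearest":
        r = np.rint(rows).astype(np.int64)
        c = np.rint(cols).astype(np.int64)
        return image[r, c]
    if interp != "bilinear":
        raise ValueError(f"unknown interpolation {interp!r}")
    img = image.astype(np.float64)
    r0 = np.minimum(np.floor(rows).astype(np.int64), max(h - 2, 0))
    c0 = np.minimum(np.floor(cols).astype(np.int64), max(w - 2, 0))
    ar = rows - r0
    ac = cols - c0
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    out = ((1 - ar) * (1 - ac) * img[r0, c0]
           + (1 - ar) * ac * img[r0, c1]
           + ar * (1 - ac) * img[r1, c0]
           + ar * ac * img[r1, c1])
    return out.astype(image.dtype if np.issubdtype(image.dtype, np.floating) else np.float64)


def warp_labeled_mask(mask: np.ndarray, dvf: np.ndarray) -> np.ndarray:
    """Warp an integer-labeled mask with nearest-neighbour sampling."""
    out = spatial_transform(mask.astype(np.int64), dvf, interp="nearest")
    return out.astype(mask.dtype)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class MotionNet:
    """Encoder -> latent LSTM rollout -> DVF decoder -> spatial transformer.

    Parameters
    ----------
    image_size : side length of the (square) input, divisible by 16, >= 32.
    base_channels : channel width of the first encoder block; doubles per level.
    latent_dim : length of the bottleneck latent vector (default 512).
    lstm_layers : recurrent depth of the rollout cell (default 2).
    n_steps : number of predicted phases (default 9, i.e. p1..p9).
    max_disp : displacement bound in pixels applied through a tanh head
        (default 0.25 * image_size).
    seed : parameter-initialisation seed.
    """

    N_LEVELS = 4

    def __init__(self, image_size: int = 32, base_channels: int = 8,
                 latent_dim: int = LATENT_DIM_DEFAULT, lstm_layers: int = 2,
                 n_steps: int = N_STEPS_DEFAULT, max_disp: float | None = None,
                 seed: int = 0):
        if image_size % 16 != 0 or image_size < 32:
            raise ValueError(
                f"image_size must be >= 32 and divisible by 16 (4 pooling levels), got {image_size}"
            )
        self.image_size = int(image_size)
        self.base_channels = int(base_channels)
        self.latent_dim = int(latent_dim)
        self.lstm_layers = int(lstm_layers)
        self.n_steps = int(n_steps)
        self.max_disp = float(max_disp) if max_disp is not None else 0.25 * image_size
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        b = self.base_channels
        chans = [b * (2 ** l) for l in range(self.N_LEVELS)]  # 1x,2x,4x,8x

        self.enc_blocks: list[tuple[Conv3, Conv3]] = []
        cin = 1
        for c in chans:
            self.enc_blocks.append((Conv3(cin, c, rng), Conv3(c, c, rng)))
            cin = c
        s16 = self.image_size // 16
        self.bottleneck = Conv3(chans[-1], chans[-1], rng)
        self.fc_enc = Linear(chans[-1] * s16 * s16, self.latent_dim, rng)
        self.lstm = [
            LSTMCell(self.latent_dim, self.latent_dim, rng) for _ in range(self.lstm_layers)
        ]
        self.fc_dec = Linear(self.latent_dim, chans[-1] * s16 * s16, rng)
        # decoder blocks, deepest first; input = upsampled features + skip
        self.dec_blocks: list[tuple[Conv3, Conv3]] = []
        cin = chans[-1]
        dec_out = [chans[2], chans[1], chans[0], chans[0]]
        for skip_c, cout in zip(reversed(chans), dec_out):
            self.dec_blocks.append((Conv3(cin + skip_c, cout, rng), Conv3(cout, cout, rng)))
            cin = cout
        self.head = Conv3(dec_out[-1], 2, rng, zero_init=True)
        self._s16 = s16
        self._chans = chans

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for l, (c1, c2) in enumerate(self.enc_blocks):
            out.update(c1.params(f"enc{l}a"))
            out.update(c2.params(f"enc{l}b"))
        out.update(self.bottleneck.params("bottleneck"))
        out.update(self.fc_enc.params("fc_enc"))
        for l, cell in enumerate(self.lstm):
            out.update(cell.params(f"lstm{l}"))
        out.update(self.fc_dec.params("fc_dec"))
        for l, (c1, c2) in enumerate(self.dec_blocks):
            out.update(c1.params(f"dec{l}a"))
            out.update(c2.params(f"dec{l}b"))
        out.update(self.head.params("head"))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameters in state dict: {sorted(missing)[:4]} ...")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def arch_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "base_channels": self.base_channels,
            "latent_dim": self.latent_dim,
            "lstm_layers": self.lstm_layers,
            "n_steps": self.n_steps,
            "max_disp": self.max_disp,
        }

    # -- forward pieces --------------------------------------------------------
    def _validate_input(self, p0: np.ndarray):
        s = self.image_size
        if p0.shape[-2:] != (s, s):
            raise ValueError(f"expected {s}x{s} input, got {p0.shape[-2:]}")

    def encode_batch(self, p0: Tensor) -> tuple[Tensor, list[Tensor]]:
        """(B,1,H,W) -> latent (B, latent_dim) plus per-level skip features."""
        x = p0
        skips: list[Tensor] = []
        for c1, c2 in self.enc_blocks:
            x = ad.relu(c1(x))
            x = ad.relu(c2(x))
            skips.append(x)
            x = ad.maxpool2(x)
        x = ad.relu(self.bottleneck(x))
        n = x.shape[0]
        flat = ad.reshape(x, (n, self._chans[-1] * self._s16 * self._s16))
        return self.fc_enc(flat), skips

    def rollout_batch(self, x0: Tensor) -> list[Tensor]:
        """Autoregressive one-to-many rollout: x0 -> [x1 .. x_{n_steps}]."""
        n = x0.shape[0]
        zeros = [Tensor(np.zeros((n, self.latent_dim), dtype=np.float32))
                 for _ in range(2 * self.lstm_layers)]
        h = zeros[: self.lstm_layers]
        c = zeros[self.lstm_layers:]
        xs: list[Tensor] = []
        x = x0
        for _ in range(self.n_steps):
            inp = x
            for l, cell in enumerate(self.lstm):
                h[l], c[l] = cell.step(inp, h[l], c[l])
                inp = h[l]
            x = h[-1]
            xs.append(x)
        return xs

    def decode_batch(self, latents: Tensor, skips: list[Tensor]) -> Tensor:
        """(M, latent_dim) + congruent skips -> DVFs (M, 2, H, W)."""
        m = latents.shape[0]
        x = self.fc_dec(latents)
        x = ad.relu(x)
        x = ad.reshape(x, (m, self._chans[-1], self._s16, self._s16))
        for (c1, c2), skip in zip(self.dec_blocks, reversed(skips)):
            x = ad.upsample2(x)
            if skip.shape[0] != m:
                raise ValueError("skip features do not match decoder batch")
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(
                    f"mismatched skip shape {skip.shape} for decoder level at {x.shape}"
                )
            x = ad.concat([x, skip], axis=1)
            x = ad.relu(c1(x))
            x = ad.relu(c2(x))
        return ad.tanh(self.head(x)) * self.max_disp

    def forward_batch(self, p0: Tensor) -> tuple[Tensor, Tensor]:
        """(B,1,H,W) -> DVFs (B, n_steps, 2, H, W) and warps (B, n_steps, 1, H, W)."""
        self._validate_input(p0.data)
        b = p0.shape[0]
        s = self.image_size
        x0, skips = self.encode_batch(p0)
        lat = self.rollout_batch(x0)
        lat_flat = ad.concat([ad.reshape(x, (b, 1, self.latent_dim)) for x in lat], axis=1)
        lat_flat = ad.reshape(lat_flat, (b * self.n_steps, self.latent_dim))
        skips_t = [ad.repeat_batch(sk, self.n_steps) for sk in skips]
        dvf = self.decode_batch(lat_flat, skips_t)
        p0_t = ad.repeat_batch(p0, self.n_steps)
        pred = ad.grid_sample_bilinear(p0_t, dvf)
        dvfs = ad.reshape(dvf, (b, self.n_steps, 2, s, s))
        preds = ad.reshape(pred, (b, self.n_steps, 1, s, s))
        return dvfs, preds

    # -- numpy-facing conveniences ---------------------------------------------
    def encode(self, p0: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Single 2D image -> (latent vector, skip feature grids)."""
        self._validate_input(np.asarray(p0))
        with ad.no_grad():
            x0, skips = self.encode_batch(Tensor(np.asarray(p0)[None, None]))
        return x0.data[0], [s.data[0] for s in skips]

    def rollout_latents(self, x0: np.ndarray) -> list[np.ndarray]:
        """Latent vector of p0 -> the n_steps subsequent latent vectors."""
        x0 = np.asarray(x0, dtype=np.float32)
        if x0.shape != (self.latent_dim,):
            raise ValueError(f"latent must have length {self.latent_dim}")
        with ad.no_grad():
            xs = self.rollout_batch(Tensor(x0[None]))
        return [x.data[0] for x in xs]

    def decode_dvf(self, x_t: np.ndarray, skips: list[np.ndarray]) -> np.ndarray:
        """One latent vector + p0 skip features -> a single (2, H, W) DVF."""
        with ad.no_grad():
            out = self.decode_batch(
                Tensor(np.asarray(x_t, dtype=np.float32)[None]),
                [Tensor(np.asarray(s)[None]) for s in skips],
            )
        return out.data[0]

    def forward(self, p0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """2D EOI image -> (DVFs (n_steps,2,H,W), predicted phases (n_steps,H,W))."""
        p0 = np.asarray(p0, dtype=np.float32)
        self._validate_input(p0)
        with ad.no_grad():
            dvfs, preds = self.forward_batch(Tensor(p0[None, None]))
        return dvfs.data[0], preds.data[0, :, 0]

    predict = forward


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _arch_hash(arch: dict) -> str:
    return hashlib.sha256(json.dumps(arch, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RMSCheckpoint:
    """Trained parameters plus everything needed to rebuild the network."""

    arch: dict
    params: dict[str, np.ndarray]
    config: dict = field(default_factory=dict)
    seed: int = 0
    epoch: int = 0
    history: list[dict] = field(default_factory=list)
    optimizer_state: dict | None = None
    rng_state: dict | None = None

    @property
    def arch_hash(self) -> str:
        return _arch_hash(self.arch)

    def build_net(self) -> MotionNet:
        net = MotionNet(seed=self.seed, **self.arch)
        net.load_state_dict(self.params)
        return net

    def save(self, path):
        meta = {
            "arch": self.arch,
            "arch_hash": self.arch_hash,
            "config": self.config,
            "seed": self.seed,
            "epoch": self.epoch,
            "history": self.history,
            "rng_state": self.rng_state,
        }
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        if self.optimizer_state is not None:
            for k, v in self.optimizer_state.items():
                if isinstance(v, np.ndarray):
                    arrays[f"opt::{k}"] = v
                else:
                    meta.setdefault("opt_scalars", {})[k] = v
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "RMSCheckpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {}
            opt: dict = dict(meta.get("opt_scalars", {}))
            has_opt = bool(meta.get("opt_scalars"))
            for k in z.files:
                if k.startswith("param::"):
                    params[k[len("param::"):]] = z[k]
                elif k.startswith("opt::"):
                    opt[k[len("opt::"):]] = z[k]
                    has_opt = True
        ck = cls(
            arch=meta["arch"],
            params=params,
            config=meta.get("config", {}),
            seed=int(meta.get("seed", 0)),
            epoch=int(meta.get("epoch", 0)),
            history=meta.get("history", []),
            optimizer_state=opt if has_opt else None,
            rng_state=meta.get("rng_state"),
        )
        if meta.get("arch_hash") and meta["arch_hash"] != ck.arch_hash:
            raise ValueError("checkpoint architecture hash mismatch")
        return ck
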