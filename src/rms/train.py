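"""Seeded training loop binding phantom data, network and losses.

The per-case objective matches the loss module: ``w_s * L_smooth +
w_m * L_MSE - w_n * L_NCC`` computed on the nine predicted phases, averaged
over the cases of a mini-batch. Training is fully deterministic given
``(dataset, TrainConfig)``: parameter initialisation, batch shuffling and
every numerical kernel derive from the config seed.

The phantom cohort may be stored at a higher resolution than the network
trains at (the default: 64 px data, 32 px training); images are block-mean
downsampled on load and predicted displacement fields are bilinearly
upsampled (and rescaled) back to data resolution for evaluation — see
:func:`downsample_image` / :func:`upsample_dvf`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import map_coordinates

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Adam
from .losses import mse_loss, ncc_loss, smoothness_loss
from .model import MotionNet, RMSCheckpoint
from .phantom import PhantomCase, iter_split

__all__ = [
    "TrainConfig",
    "train",
    "resume",
    "downsample_image",
    "upsample_dvf",
    "fit_cases",
]


@dataclass
class TrainConfig:
    """Desk-scale training configuration (YAML round-trippable)."""

    epochs: int = 90
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    smooth_weight: float = 0.05
    mse_weight: float = 30.0
    ncc_weight: float = 1.0
    ncc_window: int = 9
    image_size: int = 32
    base_channels: int = 8
    latent_dim: int = 512
    lstm_layers: int = 2
    max_disp: float | None = None
    val_interval: int = 5
    checkpoint_dir: str | None = None
    log_path: str | None = None
    device: str = "cpu"

    def __post_init__(self):
        for name in ("epochs",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("batch_size", "learning_rate", "ncc_window", "image_size",
                     "base_channels", "latent_dim", "lstm_layers", "val_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is provided")

    # -- serialisation -------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "TrainConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls(**(yaml.safe_load(text) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def arch_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "base_channels": self.base_channels,
            "latent_dim": self.latent_dim,
            "lstm_layers": self.lstm_layers,
            "n_steps": 9,
            "max_disp": (self.max_disp if self.max_disp is not None
                         else 0.25 * self.image_size),
        }


# ---------------------------------------------------------------------------
# resolution adapters
# ---------------------------------------------------------------------------

def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling by an integer factor."""
    if factor == 1:
        return np.asarray(image, dtype=np.float32)
    h, w = image.shape
    if h % factor or w % factor:
        raise ValueError(f"image size {h}x{w} not divisible by factor {factor}")
    out = image.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
    return out.astype(np.float32)


def upsample_dvf(dvf: np.ndarray, factor: int) -> np.ndarray:
    """Bilinearly upsample a (2, h, w) field by ``factor`` and rescale the
    displacements to the finer pixel grid."""
    if factor == 1:
        return np.asarray(dvf, dtype=np.float32)
    _, h, w = dvf.shape
    hh, ww = h * factor, w * factor
    # align-corners=False mapping: fine pixel centre -> coarse coordinates
    rr = (np.arange(hh) + 0.5) / factor - 0.5
    cc = (np.arange(ww) + 0.5) / factor - 0.5
    grid = np.meshgrid(rr, cc, indexing="ij")
    out = np.stack([
        map_coordinates(dvf[ch], grid, order=1, mode="nearest")
        for ch in range(2)
    ])
    return (out * factor).astype(np.float32)


def _resolution_factor(case_size: int, train_size: int) -> int:
    if case_size % train_size:
        raise ValueError(
            f"dataset resolution {case_size} must be an integer multiple of "
            f"the training resolution {train_size}"
        )
    return case_size // train_size


def _case_tensors(case: PhantomCase, train_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(p0 (1,s,s), targets (9,1,s,s)) at training resolution."""
    factor = _resolution_factor(case.images.shape[-1], train_size)
    imgs = np.stack([downsample_image(im, factor) for im in case.images])
    return imgs[0][None], imgs[1:, None]


# ---------------------------------------------------------------------------
# core loop
# ---------------------------------------------------------------------------

def _batch_loss(net: MotionNet, p0: Tensor, gt: Tensor, cfg: TrainConfig):
    """Weighted total loss over a batch; returns (Tensor, component dict)."""
    b = p0.shape[0]
    s = net.image_size
    dvfs, preds = net.forward_batch(p0)
    dvf_flat = ad.reshape(dvfs, (b * 9, 2, s, s))
    pred_flat = ad.reshape(preds, (b * 9, 1, s, s))
    gt_flat = ad.reshape(gt, (b * 9, 1, s, s))
    smooth = smoothness_loss(dvf_flat) * (1.0 / b)
    mse = mse_loss(pred_flat, gt_flat) * (1.0 / b)
    ncc = ncc_loss(pred_flat, gt_flat, window=cfg.ncc_window)
    total = smooth * cfg.smooth_weight + mse * cfg.mse_weight - ncc * cfg.ncc_weight
    comps = {
        "smooth": float(smooth.data),
        "mse": float(mse.data),
        "ncc": float(ncc.data),
        "total": float(total.data),
    }
    return total, comps


def _eval_loss(net: MotionNet, stacks, cfg: TrainConfig) -> float:
    tot, n = 0.0, 0
    with ad.no_grad():
        for p0, gt in stacks:
            _, comps = _batch_loss(net, Tensor(p0[None]), Tensor(gt[None]), cfg)
            tot += comps["total"]
            n += 1
    return tot / max(n, 1)


def fit_cases(train_cases: list[PhantomCase], val_cases: list[PhantomCase],
              config: TrainConfig, *, net: MotionNet | None = None,
              optimizer: Adam | None = None, start_epoch: int = 0,
              history: list[dict] | None = None,
              rng_state: dict | None = None) -> RMSCheckpoint:
    """Run (or continue) the training loop over in-memory phantom cases."""
    if not train_cases:
        raise ValueError("training split is empty")
    cfg = config
    net = net or MotionNet(seed=cfg.seed, **cfg.arch_dict())
    params = net.parameters()
    opt = optimizer or Adam(params, lr=cfg.learning_rate)
    history = list(history or [])
    rng = np.random.default_rng(cfg.seed + 1)
    if rng_state is not None:
        rng.bit_generator.state = rng_state

    train_stacks = [_case_tensors(c, cfg.image_size) for c in train_cases]
    val_stacks = [_case_tensors(c, cfg.image_size) for c in val_cases]

    log_fh = open(cfg.log_path, "a") if cfg.log_path else None
    best_val, best_params, best_epoch = np.inf, None, -1
    try:
        for epoch in range(start_epoch, cfg.epochs):
            order = rng.permutation(len(train_stacks))
            comps_sum = {"smooth": 0.0, "mse": 0.0, "ncc": 0.0, "total": 0.0}
            n_steps = 0
            for lo in range(0, len(order), cfg.batch_size):
                idx = order[lo: lo + cfg.batch_size]
                p0 = Tensor(np.stack([train_stacks[i][0] for i in idx]))
                gt = Tensor(np.stack([train_stacks[i][1] for i in idx]))
                opt.zero_grad()
                total, comps = _batch_loss(net, p0, gt, cfg)
                if not np.isfinite(comps["total"]):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {comps}"
                    )
                total.backward()
                opt.step()
                for k in comps_sum:
                    comps_sum[k] += comps[k]
                n_steps += 1
            row = {"epoch": epoch}
            row.update({k: v / n_steps for k, v in comps_sum.items()})
            if val_stacks and ((epoch + 1) % cfg.val_interval == 0
                               or epoch == cfg.epochs - 1):
                row["val_total"] = _eval_loss(net, val_stacks, cfg)
                if row["val_total"] < best_val:
                    best_val = row["val_total"]
                    best_params = net.state_dict()
                    best_epoch = epoch
            history.append(row)
            if log_fh:
                log_fh.write(json.dumps(row) + "\n")
                log_fh.flush()
    finally:
        if log_fh:
            log_fh.close()

    ck = RMSCheckpoint(
        arch=net.arch_dict(),
        params=net.state_dict(),
        config=dict(asdict(cfg), config_hash=cfg.config_hash(),
                    best_epoch=best_epoch, best_val=None if best_epoch < 0 else best_val),
        seed=cfg.seed,
        epoch=cfg.epochs,
        history=history,
        optimizer_state=opt.state_dict(),
        rng_state=rng.bit_generator.state,
    )
    if cfg.checkpoint_dir:
        out = Path(cfg.checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        ck.save(out / "checkpoint.npz")
        if best_params is not None:
            best = RMSCheckpoint(arch=net.arch_dict(), params=best_params,
                                 config=ck.config, seed=cfg.seed, epoch=best_epoch + 1,
                                 history=history)
            best.save(out / "checkpoint_best.npz")
        pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    return ck


def train(dataset_dir, config: TrainConfig | None = None) -> tuple[RMSCheckpoint, pd.DataFrame]:
    """Train on a phantom dataset directory; the held-out test split doubles
    as the validation set for best-checkpoint selection."""
    cfg = config or TrainConfig()
    train_cases = list(iter_split(dataset_dir, "train"))
    val_cases = list(iter_split(dataset_dir, "test"))
    ck = fit_cases(train_cases, val_cases, cfg)
    return ck, pd.DataFrame(ck.history)


def resume(checkpoint: RMSCheckpoint | str, dataset_dir, config: TrainConfig
           ) -> tuple[RMSCheckpoint, pd.DataFrame]:
    """Continue training from a checkpoint up to ``config.epochs``."""
    ck = (checkpoint if isinstance(checkpoint, RMSCheckpoint)
          else RMSCheckpoint.load(checkpoint))
    from .model import _arch_hash
    if _arch_hash(config.arch_dict()) != ck.arch_hash:
        raise ValueError("checkpoint architecture does not match the config")
    if ck.epoch >= config.epochs:
        return ck, pd.DataFrame(ck.history)
    net = ck.build_net()
    opt = Adam(net.parameters(), lr=config.learning_rate)
    if ck.optimizer_state is not None:
        opt.load_state_dict(ck.optimizer_state)
    train_cases = list(iter_split(dataset_dir, "train"))
    val_cases = list(iter_split(dataset_dir, "test"))
    out = fit_cases(train_cases, val_cases, config, net=net, optimizer=opt,
                    start_epoch=ck.epoch, history=ck.history,
                    rng_state=ck.rng_state)
    return out, pd.DataFrame(out.history)
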