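"""Training losses: DVF smoothness, image MSE, and windowed local NCC.

All three are written against the autodiff tape so the same code drives
training and (via plain arrays) evaluation/testing. Conventions:

* ``smoothness_loss`` — forward finite differences of each displacement
  channel in both directions, squared, summed over pixels, channels and
  phases, divided by ``2 N`` with ``N`` the pixels per field. Edge rows and
  columns use replication (zero gradient at the last row/col).
* ``mse_loss`` — per-phase mean over pixels of the squared intensity
  difference, summed over phases. The per-pixel mean (rather than a bare
  sum) keeps loss weights resolution-independent.
* ``ncc_loss`` — squared local normalized cross-correlation in a sliding
  window (default 9x9), averaged over pixels and phases. It is a similarity
  in [0, 1] (up to the stabilising epsilon): 1 for a perfect (even affinely
  rescaled) match. The combined training objective therefore *subtracts* it:
  ``L = w_s * L_smooth + w_m * L_MSE - w_n * L_NCC``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "LossBreakdown",
    "smoothness_loss",
    "mse_loss",
    "ncc_loss",
    "total_loss",
    "NCC_EPS",
]

NCC_EPS = 1e-5


@dataclass(frozen=True)
class LossBreakdown:
    """Scalar loss components; ``total = smooth + mse - ncc`` (weighted)."""

    smooth: float
    mse: float
    ncc: float
    total: float


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float32)), False


def _ret(value: Tensor, symbolic: bool):
    return value if symbolic else float(value.data)


def _diff(x: Tensor, axis: int) -> Tensor:
    n = x.shape[axis]
    return ad.narrow(x, axis, 1, n - 1) - ad.narrow(x, axis, 0, n - 1)


def smoothness_loss(dvfs):
    """Gradient penalty of one or more displacement fields.

    Accepts ``(2, H, W)``, ``(T, 2, H, W)`` or a congruent :class:`Tensor`;
    sums over phases, divides by ``2 * H * W``.
    """
    t, symbolic = _as_tensor(dvfs)
    if t.ndim == 3:
        t = ad.reshape(t, (1,) + t.shape)
    if t.ndim != 4 or t.shape[1] != 2:
        raise ValueError(f"expected (T, 2, H, W) displacement fields, got {t.shape}")
    n_pix = t.shape[2] * t.shape[3]
    dh = _diff(t, 2)
    dw = _diff(t, 3)
    total = ad.tsum(ad.square(dh)) + ad.tsum(ad.square(dw))
    return _ret(total * (1.0 / (2.0 * n_pix)), symbolic)


def _phase_images(x) -> tuple[Tensor, bool]:
    t, symbolic = _as_tensor(x)
    if t.ndim == 2:
        t = ad.reshape(t, (1, 1) + t.shape)
    elif t.ndim == 3:
        t = ad.reshape(t, (t.shape[0], 1, t.shape[1], t.shape[2]))
    if t.ndim != 4:
        raise ValueError(f"expected phase image stack, got shape {t.shape}")
    return t, symbolic


def mse_loss(pred, gt):
    """Per-pixel mean squared difference, summed over phases."""
    p, sp = _phase_images(pred)
    g, sg = _phase_images(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    n_pix = p.shape[1] * p.shape[2] * p.shape[3]
    out = ad.tsum(ad.square(p - g)) * (1.0 / n_pix)
    return _ret(out, sp or sg)


def ncc_loss(pred, gt, window: int = 9, eps: float = NCC_EPS):
    """Squared local normalized cross-correlation, averaged over pixels/phases.

    Local sums use zero padding with an exact per-pixel window count, so
    border statistics are true means over the in-frame part of the window.
    """
    p, sp = _phase_images(pred)
    g, sg = _phase_images(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    h, w = p.shape[2], p.shape[3]
    if window > min(h, w):
        raise ValueError(f"window {window} exceeds image size {h}x{w}")
    ones = Tensor(np.ones((1, 1, h, w), dtype=np.float32))
    n = ad.box_sum(ones, window)  # per-pixel in-frame window size
    inv_n = Tensor(1.0 / n.data)

    s_g = ad.box_sum(g, window)
    s_p = ad.box_sum(p, window)
    s_gg = ad.box_sum(g * g, window)
    s_pp = ad.box_sum(p * p, window)
    s_gp = ad.box_sum(g * p, window)
    u_g = s_g * inv_n
    u_p = s_p * inv_n
    cross = s_gp - u_g * s_p
    var_g = ad.relu(s_gg - u_g * s_g)
    var_p = ad.relu(s_pp - u_p * s_p)
    cc = ad.square(cross) * ad.powi(var_g * var_p + eps, -1.0)
    return _ret(ad.tmean(cc), sp or sg)


def total_loss(dvfs, pred, gt, weights=(1.0, 1.0, 1.0), window: int = 9):
    """Combine the three components; returns a :class:`LossBreakdown` for
    array inputs or ``(total Tensor, LossBreakdown)`` for Tensor inputs."""
    w_s, w_m, w_n = (float(x) for x in weights)
    smooth = smoothness_loss(dvfs)
    mse = mse_loss(pred, gt)
    ncc = ncc_loss(pred, gt, window=window)
    if isinstance(smooth, Tensor) or isinstance(mse, Tensor):
        total = smooth * w_s + mse * w_m - ncc * w_n
        bd = LossBreakdown(float(smooth.data), float(mse.data), float(ncc.data),
                           float(total.data))
        return total, bd
    total = w_s * smooth + w_m * mse - w_n * ncc
    return LossBreakdown(smooth, mse, ncc, total)
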