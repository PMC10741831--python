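"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a small convolutional/recurrent network on the CPU, so it
carries its own dependency-light tape-based autodiff: a :class:`Tensor` wraps
a float32 ``numpy`` array and records enough of the computation graph to
backpropagate. Only the operations the motion network needs are provided
(elementwise arithmetic, matmul, 3x3 same-padding convolution, 2x2 max
pooling, nearest upsampling, bilinear grid sampling, windowed box sums and a
few nonlinearities). Every op is validated against finite differences in the
test suite.

Conventions: image tensors are NCHW; displacement fields are (N, 2, H, W)
with channel 0 the column (x) displacement and channel 1 the row (y)
displacement, in pixels, backward-warping.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate1d

__all__ = ["Tensor", "Parameter", "no_grad"]

_F32 = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array plus the tape entry needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bwd=None):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or (
            _GRAD_ENABLED and any(p.requires_grad for p in _parents)
        )
        self._parents = _parents if self.requires_grad else ()
        self._bwd = _bwd if self.requires_grad else None

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- graph -------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (LSTM rollout)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=_F32)
        )
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)
            # free interior tape state eagerly; keep leaf grads
            if node._parents:
                node._bwd = None

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, powi(other, -1.0))


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=_F32), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _const(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=_F32))


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=_F32, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reductions
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._bwd = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._bwd = bwd
    return out


def powi(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data ** p, _parents=(a,))

    def bwd(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    out._bwd = bwd
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data * a.data, _parents=(a,))

    def bwd(g):
        _accum(a, g * 2.0 * a.data)

    out._bwd = bwd
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))

    def bwd(g):
        _accum(a, g * (a.data > 0))

    out._bwd = bwd
    return out


def tanh(a: Tensor) -> Tensor:
    v = np.tanh(a.data)
    out = Tensor(v, _parents=(a,))

    def bwd(g):
        _accum(a, g * (1.0 - v * v))

    out._bwd = bwd
    return out


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit

    v = expit(a.data)
    out = Tensor(v, _parents=(a,))

    def bwd(g):
        _accum(a, g * v * (1.0 - v))

    out._bwd = bwd
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def bwd(g):
        gg = np.asarray(g, dtype=_F32)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    out._bwd = bwd
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), _const(1.0 / float(n)))


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    out._bwd = bwd
    return out


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    out._bwd = bwd
    return out


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = Tensor(a.data[sl], _parents=(a,))

    def bwd(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        _accum(a, full)

    out._bwd = bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            _accum(a, g @ b.data.swapaxes(-1, -2))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    out._bwd = bwd
    return out


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*9) patch matrix for 3x3 same-padding conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * 9)


def _conv3_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 stride-1 zero-padded correlation; x (N,C,H,W), w (F,C,3,3)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    cols = _im2col3(x)
    out = cols @ w.reshape(f, c * 9).T  # (N, HW, F)
    return out.transpose(0, 2, 1).reshape(n, f, h, wd)


def conv3x3(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding 3x3 convolution (cross-correlation), stride 1."""
    n, c, h, wd = x.data.shape
    f = w.data.shape[0]
    cols = _im2col3(x.data)
    val = (cols @ w.data.reshape(f, c * 9).T).transpose(0, 2, 1).reshape(n, f, h, wd)
    if b is not None:
        val = val + b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, _parents=parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            g2 = g.reshape(n, f, h * wd)  # (N,F,HW)
            dw = np.einsum("nfi,nik->fk", g2, cols, optimize=True)
            _accum(w, dw.reshape(f, c, 3, 3))
        if x.requires_grad:
            # transpose conv == conv with channel-swapped, spatially flipped kernel
            wt = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            _accum(x, _conv3_raw(g, wt))

    out._bwd = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    val = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(val, _parents=(x,))

    def bwd(g):
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, gr.reshape(n, c, h, w))

    out._bwd = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    val = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(val, _parents=(x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._bwd = bwd
    return out


def _bilinear_gather(img: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    """Shared forward kernel for bilinear sampling with border clamping.

    img (N,C,H,W); rows/cols (N,H,W) absolute sampling coordinates.
    Returns value plus the pieces the backward pass needs.
    """
    n, c, h, w = img.shape
    rc = np.clip(rows, 0.0, h - 1.0)
    cc = np.clip(cols, 0.0, w - 1.0)
    r0 = np.floor(rc).astype(np.int64)
    c0 = np.floor(cc).astype(np.int64)
    r0 = np.minimum(r0, h - 2) if h > 1 else r0 * 0
    c0 = np.minimum(c0, w - 2) if w > 1 else c0 * 0
    ar = (rc - r0).astype(_F32)
    ac = (cc - c0).astype(_F32)
    ni = np.arange(n)[:, None, None]

    def gat(r, cx):  # fancy-index (N,H,W) grids across the channel axis
        return img[ni, :, r, cx].transpose(0, 3, 1, 2)

    v00 = gat(r0, c0)
    v01 = gat(r0, c0 + 1) if w > 1 else v00
    v10 = gat(r0 + 1, c0) if h > 1 else v00
    v11 = gat(r0 + 1, c0 + 1) if (h > 1 and w > 1) else v00
    arb = ar[:, None]
    acb = ac[:, None]
    val = ((1 - arb) * ((1 - acb) * v00 + acb * v01)
           + arb * ((1 - acb) * v10 + acb * v11))
    inside_r = (rows > 0.0) & (rows < h - 1.0)
    inside_c = (cols > 0.0) & (cols < w - 1.0)
    return val.astype(_F32), (r0, c0, ar, ac, v00, v01, v10, v11, inside_r, inside_c)


def grid_sample_bilinear(img: Tensor, flow: Tensor) -> Tensor:
    """Backward-warp ``img`` by ``flow`` (N,2,H,W): out(i,j) = img(i+uy, j+ux).

    Out-of-bounds samples clamp to the border. Differentiable in both
    arguments; the flow gradient is zeroed where the sample is clamped.
    """
    n, c, h, w = img.data.shape
    jj, ii = np.meshgrid(np.arange(w, dtype=_F32), np.arange(h, dtype=_F32))
    rows = ii[None] + flow.data[:, 1]
    cols = jj[None] + flow.data[:, 0]
    val, ctx = _bilinear_gather(img.data, rows, cols)
    out = Tensor(val, _parents=(img, flow))
    r0, c0, ar, ac, v00, v01, v10, v11, inside_r, inside_c = ctx

    def bwd(g):
        arb, acb = ar[:, None], ac[:, None]
        if img.requires_grad:
            gi = np.zeros_like(img.data)
            w00 = (1 - arb) * (1 - acb) * g
            w01 = (1 - arb) * acb * g
            w10 = arb * (1 - acb) * g
            w11 = arb * acb * g
            for dr, dc, wv in ((0, 0, w00), (0, 1, w01), (1, 0, w10), (1, 1, w11)):
                rr = np.minimum(r0 + dr, h - 1)
                cc2 = np.minimum(c0 + dc, w - 1)
                for b in range(n):
                    np.add.at(gi[b].transpose(1, 2, 0), (rr[b], cc2[b]),
                              wv[b].transpose(1, 2, 0))
            _accum(img, gi)
        if flow.requires_grad:
            dcol = ((1 - arb) * (v01 - v00) + arb * (v11 - v10)) * g
            drow = ((1 - acb) * (v10 - v00) + acb * (v11 - v01)) * g
            gf = np.empty_like(flow.data)
            gf[:, 0] = dcol.sum(axis=1) * inside_c
            gf[:, 1] = drow.sum(axis=1) * inside_r
            _accum(flow, gf)

    out._bwd = bwd
    return out


def box_sum(x: Tensor, win: int) -> Tensor:
    """Windowed sum over a win x win neighbourhood (zero padding), NCHW.

    Self-adjoint (symmetric kernel + zero padding), so backward applies the
    same filter to the incoming gradient.
    """
    if win % 2 == 0 or win < 3:
        raise ValueError("window must be odd and >= 3")
    k = np.ones(win, dtype=_F32)

    def filt(a):
        a = correlate1d(a, k, axis=-1, mode="constant", cval=0.0)
        return correlate1d(a, k, axis=-2, mode="constant", cval=0.0)

    out = Tensor(filt(x.data), _parents=(x,))

    def bwd(g):
        _accum(x, filt(g.astype(_F32)))

    out._bwd = bwd
    return out


def repeat_batch(x: Tensor, k: int) -> Tensor:
    """Repeat each batch element ``k`` times along axis 0 (contiguous blocks)."""
    out = Tensor(np.repeat(x.data, k, axis=0), _parents=(x,))
    b = x.data.shape[0]

    def bwd(g):
        _accum(x, g.reshape((b, k) + x.data.shape[1:]).sum(axis=1))

    out._bwd = bwd
    return out
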