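"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every operation returns a new
:class:`Tensor` holding a closure that propagates the output gradient to its
inputs.  All arithmetic is float32.  The op set is exactly what the detector
needs — elementwise arithmetic, matmul, reductions, indexing, concatenation,
2-D convolution (im2col + GEMM, column buffer recomputed in the backward pass
to keep memory flat), fused batch normalization, SiLU/ReLU/sigmoid gates,
stride-1 max pooling and nearest 2x upsampling.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv1d_channels",
    "batch_norm2d",
    "max_pool2d_same",
    "upsample2x",
    "bce_with_logits",
    "maximum",
    "minimum",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._children: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, children, backward):
        out = Tensor(data)
        out.requires_grad = any(c.requires_grad for c in children)
        if out.requires_grad:
            out._children = children
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    # -- basic introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- transcendental -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def arctan(self):
        a = self

        def backward(g):
            a._accum(g / (1.0 + a.data * a.data))

        return Tensor._make(np.arctan(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def silu(self):
        a = self
        s = _sigmoid(a.data)
        out_data = a.data * s

        def backward(g):
            a._accum(g * s * (1.0 + a.data * (1.0 - s)))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def clip(self, lo: float | None, hi: float | None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask *= a.data >= lo
        if hi is not None:
            mask *= a.data <= hi

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(out_data, (a,), backward)

    # -- reductions and shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                buf = np.zeros_like(a.data)
                np.add.at(buf, idx, g)
                a._accum(buf)

        return Tensor._make(a.data[idx], (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping keeps exp finite; exact to float32 precision over the
    # clipped range
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def maximum(a, b) -> Tensor:
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    mask = a.data >= b.data

    def backward(g):
        a._accum(_unbroadcast(g * mask, a.data.shape))
        b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    mask = a.data <= b.data

    def backward(g):
        a._accum(_unbroadcast(g * mask, a.data.shape))
        b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._make(np.minimum(a.data, b.data), (a, b), backward)


def concat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


# ---------------------------------------------------------------------------
# Convolution (im2col + GEMM)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return columns of shape (B, C*k*k, Ho*Wo) plus output spatial dims."""
    b, c, h, w = x.shape
    if k == 1 and stride == 1 and pad == 0:
        return x.reshape(b, c, h * w), h, w
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    col = np.empty((b, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        i_end = i + stride * ho
        for j in range(k):
            j_end = j + stride * wo
            col[:, :, i, j] = x[:, :, i:i_end:stride, j:j_end:stride]
    return col.reshape(b, c * k * k, ho * wo), ho, wo


def _col2im(dcol: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    b, c, h, w = x_shape
    if k == 1 and stride == 1 and pad == 0:
        return dcol.reshape(b, c, h, w)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    dcol = dcol.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        i_end = i + stride * ho
        for j in range(k):
            j_end = j + stride * wo
            dxp[:, :, i:i_end:stride, j:j_end:stride] += dcol[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


# forward column buffers below this many bytes are cached for the backward
# pass; larger ones are recomputed to keep peak memory flat
_COL_CACHE_BYTES = 64 * 1024 * 1024


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation.  weight: (Co, Ci, k, k); x: (B, Ci, H, W)."""
    co, ci, k, _ = weight.data.shape
    col, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(co, -1)
    out_data = np.matmul(wmat[None], col)           # (B, Co, Ho*Wo)
    b = x.data.shape[0]
    if bias is not None:
        out_data += bias.data[None, :, None]
    out_data = out_data.reshape(b, co, ho, wo)
    children = (x, weight) if bias is None else (x, weight, bias)
    cached_col = col if col.nbytes <= _COL_CACHE_BYTES else None

    def backward(g):
        gm = np.ascontiguousarray(g.reshape(b, co, ho * wo))
        if bias is not None:
            bias._accum(gm.sum(axis=(0, 2)))
        if weight.requires_grad:
            col2 = cached_col
            if col2 is None:
                col2, _, _ = _im2col(x.data, k, stride, pad)
            dw = np.matmul(gm, col2.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dcol = np.matmul(wmat.T[None], gm)
            x._accum(_col2im(dcol, x.data.shape, k, stride, pad, ho, wo))

    return Tensor._make(out_data, children, backward)


def conv1d_channels(x: Tensor, weight: Tensor) -> Tensor:
    """Bias-free 1-D convolution along the channel axis of a (B, C) tensor.

    Zero padding of k//2 keeps the length; the kernel is shared across
    channels (the efficient-channel-attention convolution).
    """
    (k,) = weight.data.shape
    p = k // 2
    b, c = x.data.shape
    xp = np.pad(x.data, ((0, 0), (p, p)))
    out_data = np.zeros((b, c), dtype=x.data.dtype)
    for j in range(k):
        out_data += weight.data[j] * xp[:, j:j + c]

    def backward(g):
        if weight.requires_grad:
            dw = np.array([(g * xp[:, j:j + c]).sum() for j in range(k)],
                          dtype=np.float32)
            weight._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, j:j + c] += weight.data[j] * g
            x._accum(dxp[:, p:p + c])

    return Tensor._make(out_data, (x, weight), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Fused batch norm over (B, H, W) per channel with affine parameters.

    Running statistics are updated in place when ``training`` is true.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxh = g * gamma.data[None, :, None, None]
        if training:
            m1 = gxh.mean(axis=(0, 2, 3))
            m2 = (gxh * xhat).mean(axis=(0, 2, 3))
            dx = (gxh - m1[None, :, None, None]
                  - xhat * m2[None, :, None, None]) * invstd[None, :, None, None]
        else:
            dx = gxh * invstd[None, :, None, None]
        x._accum(dx)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def max_pool2d_same(x: Tensor, k: int) -> Tensor:
    """Stride-1 max pooling with 'same' padding (spatial-pyramid pools)."""
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf)
    b, c, h, w = x.data.shape
    out_data = np.full((b, c, h, w), -np.inf, dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            np.maximum(out_data, xp[:, :, i:i + h, j:j + w], out=out_data)

    def backward(g):
        dxp = np.zeros_like(xp)
        remaining = np.ones_like(g, dtype=bool)
        for i in range(k):
            for j in range(k):
                hit = (xp[:, :, i:i + h, j:j + w] == out_data) & remaining
                dxp[:, :, i:i + h, j:j + w] += g * hit
                remaining &= ~hit
        x._accum(dxp[:, :, p:p + h, p:p + w])

    return Tensor._make(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    a = x
    out_data = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        b, c, h2, w2 = g.shape
        a._accum(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (a,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with a numerically stable log-sum-exp form."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = max(z.size, 1)
    out_data = loss.sum() / n

    def backward(g):
        logits._accum(g * (_sigmoid(z) - t) / n)

    return Tensor._make(out_data, (logits,), backward)
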