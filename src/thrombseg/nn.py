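"""Minimal reverse-mode autodiff engine for 3-D segmentation networks.

A deliberately small numpy engine providing exactly the operations the
U-Net variants need: 3-D convolution (kernel 3 / padding 1 and 1x1x1),
ReLU, 2x max pooling, 2x trilinear up-sampling with aligned corners,
channel concatenation, elementwise addition, per-channel weighted fusion,
and a weighted sigmoid cross-entropy loss -- each with a hand-derived
backward pass.  Tensors carry no batch axis; volumes are (C, D, H, W) and
training runs one crop at a time.

Convolutions are lowered to matrix multiplies via im2col; the input
gradient scatters the GEMM result back through the 27 kernel offsets.
Tensors preserve their input float dtype: layer parameters are float32
(BLAS throughput), while standalone loss/fusion evaluations on float64
inputs stay float64.  Everything is deterministic in single-threaded
execution.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Iterable, List, Sequence, Tuple

import numpy as np


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        order: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def _node(data: np.ndarray, parents: Tuple[Tensor, ...],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    needs = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, parents=parents if needs else (),
                  backward=backward if needs else None)


# ---------------------------------------------------------------------------
# ops

def conv3d(x: Tensor, weight: Tensor, bias: Tensor,
           kernel: int = 3, padding: int = 1) -> Tensor:
    """Same-size 3-D convolution of (Cin, D, H, W) with (Cout, Cin, k, k, k)."""
    k = kernel
    if k == 1:
        w2 = weight.data[..., 0, 0, 0]  # (Cout, Cin)
        y = np.einsum("oi,idhw->odhw", w2, x.data, optimize=True)
        y += bias.data[:, None, None, None]

        def back(gy: np.ndarray) -> None:
            if weight.requires_grad:
                gw = np.einsum("odhw,idhw->oi", gy, x.data, optimize=True)
                weight._accumulate(gw[..., None, None, None])
            if bias.requires_grad:
                bias._accumulate(gy.sum(axis=(1, 2, 3)))
            gx = np.einsum("oi,odhw->idhw", w2, gy, optimize=True)
            x._accumulate(gx)

        return _node(y, (x, weight, bias), back)

    ci, d, h, w = x.shape
    co = weight.shape[0]
    pad = [(0, 0)] + [(padding, padding)] * 3
    xp = np.pad(x.data, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    # im2col: rows ordered (channel, kz, ky, kx), columns are voxels
    col = np.ascontiguousarray(win.transpose(0, 4, 5, 6, 1, 2, 3)).reshape(ci * k**3, -1)
    wmat = weight.data.reshape(co, ci * k**3)
    y = (wmat @ col).reshape(co, d, h, w)
    y += bias.data[:, None, None, None]

    def back(gy: np.ndarray) -> None:
        gmat = gy.reshape(co, -1)
        if weight.requires_grad:
            weight._accumulate((gmat @ col.T).reshape(weight.shape))
        if bias.requires_grad:
            bias._accumulate(gy.sum(axis=(1, 2, 3)))
        gcol = (wmat.T @ gmat).reshape(ci, k, k, k, d, h, w)
        gxp = np.zeros_like(xp)
        for a in range(k):  # scatter col gradients back through kernel offsets
            for b in range(k):
                for c in range(k):
                    gxp[:, a:a + d, b:b + h, c:c + w] += gcol[:, a, b, c]
        x._accumulate(gxp[:, padding:padding + d, padding:padding + h,
                          padding:padding + w])

    return _node(y, (x, weight, bias), back)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def back(gy: np.ndarray) -> None:
        x._accumulate(gy * mask)

    return _node(y, (x,), back)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add shape mismatch {a.shape} vs {b.shape}")
    y = a.data + b.data

    def back(gy: np.ndarray) -> None:
        a._accumulate(gy)
        b._accumulate(gy)

    return _node(y, (a, b), back)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis (axis 0)."""
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"concat spatial mismatch {a.shape} vs {b.shape}")
    y = np.concatenate([a.data, b.data], axis=0)
    ca = a.shape[0]

    def back(gy: np.ndarray) -> None:
        a._accumulate(gy[:ca])
        b._accumulate(gy[ca:])

    return _node(y, (a, b), back)


def channel_weighted_sum(a: Tensor, b: Tensor, k1: Tensor, k2: Tensor) -> Tensor:
    """Per-channel fusion F_i = k1_i * A_i + k2_i * B_i (1x1x1 kernels)."""
    if a.shape != b.shape:
        raise ValueError(f"fusion shape mismatch {a.shape} vs {b.shape}")
    if k1.shape != (a.shape[0],) or k2.shape != (b.shape[0],):
        raise ValueError("one scalar pair per channel is required")
    w1 = k1.data[:, None, None, None]
    w2 = k2.data[:, None, None, None]
    y = w1 * a.data + w2 * b.data

    def back(gy: np.ndarray) -> None:
        a._accumulate(gy * w1)
        b._accumulate(gy * w2)
        if k1.requires_grad:
            k1._accumulate((gy * a.data).sum(axis=(1, 2, 3)))
        if k2.requires_grad:
            k2._accumulate((gy * b.data).sum(axis=(1, 2, 3)))

    return _node(y, (a, b, k1, k2), back)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; spatial extents must be even."""
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even extents, got {x.shape}")
    r = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    y = r.max(axis=(2, 4, 6))

    def back(gy: np.ndarray) -> None:
        ymax = y[:, :, None, :, None, :, None]
        mask = r == ymax
        counts = mask.sum(axis=(2, 4, 6), keepdims=True).astype(gy.dtype)
        g = mask * (gy[:, :, None, :, None, :, None] / counts)
        x._accumulate(g.reshape(c, d, h, w))

    return _node(y, (x,), back)


@lru_cache(maxsize=None)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D linear interpolation matrix with aligned corners, (n_out, n_in)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_trilinear2(x: Tensor) -> Tensor:
    """Double every spatial extent by trilinear interpolation, corners aligned."""
    _, d, h, w = x.shape
    md = _interp_matrix(d, 2 * d).astype(x.data.dtype)
    mh = _interp_matrix(h, 2 * h).astype(x.data.dtype)
    mw = _interp_matrix(w, 2 * w).astype(x.data.dtype)
    y = np.einsum("ai,bj,ek,cijk->cabe", md, mh, mw, x.data, optimize=True)

    def back(gy: np.ndarray) -> None:
        gx = np.einsum("ai,bj,ek,cabe->cijk", md, mh, mw, gy, optimize=True)
        x._accumulate(gx)

    return _node(y, (x,), back)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_loss(logits: Tensor, target: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean over voxels of -[w t log s(z) + (1 - t) log(1 - s(z))].

    ``pos_weight`` up-weights the foreground term to counter the extreme
    class imbalance between thrombus and background voxels.
    """
    t = np.asarray(target, dtype=logits.data.dtype)
    if t.shape != logits.data.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {logits.data.shape}")
    if pos_weight <= 0:
        raise ValueError("positive-class weight must be > 0")
    z = logits.data
    elem = pos_weight * t * _softplus(-z) + (1.0 - t) * _softplus(z)
    n = t.size
    y = np.asarray(elem.sum() / n)

    def back(gy: np.ndarray) -> None:
        s = sigmoid(z)
        gz = ((1.0 - t) * s - pos_weight * t * (1.0 - s)) / n
        logits._accumulate(gy * gz)

    return _node(y, (logits,), back)


# ---------------------------------------------------------------------------
# layers

class Conv3d:
    """Convolution layer with He-normal initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 padding: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.padding = padding
        shape = (out_channels, in_channels, kernel, kernel, kernel)
        self.weight = parameter(rng.normal(0.0, std, shape).astype(np.float32))
        self.bias = parameter(np.zeros(out_channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.kernel, self.padding)

    def parameters(self) -> List[Tensor]:
        return [self.weight, self.bias]


class ConvBlock:
    """Two 3x3x3 convolutions, each followed by ReLU."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv3d(in_channels, out_channels, rng=rng)
        self.conv2 = Conv3d(out_channels, out_channels, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.conv2(relu(self.conv1(x))))

    def parameters(self) -> List[Tensor]:
        return self.conv1.parameters() + self.conv2.parameters()


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
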