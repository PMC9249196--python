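"""Compact CPU neural-network building blocks with hand-coded backprop.

Everything runs in float32, NHWC layout, on top of numpy's BLAS-backed
matmul.  The layer set is exactly what the staging network needs: 2-D
convolution (zero or symmetric padding), depthwise convolution, batch
normalisation (4-D and 2-D), ReLU / leaky ReLU, dropout, ceil-mode 2x2
max-pooling, dense layers, a fused softmax cross-entropy, and Adam.

Convolutions use a shift-and-accumulate scheme: for every kernel offset
(i, j) the padded input slab is multiplied against the (C_in, C_out) weight
slice in a single GEMM, which is far cheaper on CPU than materialising
im2col windows.  Each layer caches what its backward pass needs during
``forward``; ``backward`` returns the gradient with respect to the layer
input and accumulates parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "Param", "Conv2D", "DepthwiseConv2D", "BatchNorm", "ReLU", "LeakyReLU",
    "Dropout", "MaxPool2x2Ceil", "Flatten", "Dense", "Adam",
    "softmax", "softmax_cross_entropy",
]


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("val", "grad", "name")

    def __init__(self, val: np.ndarray, name: str = "") -> None:
        self.val = np.ascontiguousarray(val, dtype=np.float32)
        self.grad = np.zeros_like(self.val)
        self.name = name

    @property
    def size(self) -> int:
        return self.val.size


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float32) * math.sqrt(2.0 / fan_in)


# ---------------------------------------------------------------------------
# padding helpers (NHWC: spatial axes 1 and 2)
# ---------------------------------------------------------------------------


def _pad2d(x: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return x
    spec = ((0, 0), (p, p), (p, p), (0, 0))
    if mode == "zeros":
        return np.pad(x, spec)
    if mode == "symmetric":
        return np.pad(x, spec, mode="symmetric")
    raise ValueError(f"unknown pad mode {mode!r}")


def _fold_axis(g: np.ndarray, p: int, axis: int) -> np.ndarray:
    """Fold symmetric-padding gradients back onto the unpadded extent."""
    sl = [slice(None)] * g.ndim
    sl[axis] = slice(p, g.shape[axis] - p)
    out = np.ascontiguousarray(g[tuple(sl)])

    src = [slice(None)] * g.ndim
    dst = [slice(None)] * g.ndim
    src[axis] = slice(0, p)
    dst[axis] = slice(0, p)
    out[tuple(dst)] += np.flip(g[tuple(src)], axis=axis)
    src[axis] = slice(g.shape[axis] - p, g.shape[axis])
    dst[axis] = slice(out.shape[axis] - p, out.shape[axis])
    out[tuple(dst)] += np.flip(g[tuple(src)], axis=axis)
    return out


def _fold2d(g: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return g
    if mode == "zeros":
        return np.ascontiguousarray(g[:, p:-p, p:-p, :])
    # np.pad pads the axes one after another, so fold in reverse order
    g = _fold_axis(g, p, axis=2)
    g = _fold_axis(g, p, axis=1)
    return g


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2D:
    """Same-padded 2-D convolution (cross-correlation), stride 1.

    Weights have shape (k, k, C_in, C_out) so each kernel offset contributes
    one (C_in, C_out) GEMM against the shifted input slab.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 pad_mode: str = "zeros", name: str = "conv") -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k, self.pad_mode = k, pad_mode
        fan_in = in_ch * k * k
        self.W = Param(_he_normal(rng, (k, k, in_ch, out_ch), fan_in), f"{name}.W")
        self.b = Param(np.zeros(out_ch, dtype=np.float32), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = _pad2d(x, p, self.pad_mode)
        n, h, w, c = x.shape
        out_ch = self.W.val.shape[3]
        # contiguous im2col buffer built from k*k fast slab copies,
        # then a single GEMM against the (k*k*C, O) weight matrix
        cols = np.empty((n, h, w, k * k, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i * k + j, :] = xp[:, i:i + h, j:j + w, :]
        y = cols.reshape(n * h * w, k * k * c) @ self.W.val.reshape(-1, out_ch)
        self._cols, self._hw, self._c = cols, (h, w), c
        return y.reshape(n, h, w, out_ch) + self.b.val

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        h, w = self._hw
        c = self._c
        n, _, _, out_ch = dy.shape
        dyf = dy.reshape(-1, out_ch)
        cols = self._cols.reshape(n * h * w, k * k * c)
        self.W.grad += (cols.T @ dyf).reshape(self.W.val.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.val.reshape(-1, out_ch).T)
        dcols = dcols.reshape(n, h, w, k * k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i * k + j, :]
        self._cols = None
        return _fold2d(dxp, p, self.pad_mode)


@njit(cache=True)
def _dw_forward(xp, W, y):          # pragma: no cover - exercised via layer
    n, h, w, c = y.shape
    k = W.shape[0]
    for m in range(n):
        for r in range(h):
            for s in range(w):
                for i in range(k):
                    for j in range(k):
                        for ch in range(c):
                            y[m, r, s, ch] += xp[m, r + i, s + j, ch] * W[i, j, ch]


@njit(cache=True)
def _dw_backward(xp, W, dy, dW, dxp):   # pragma: no cover - exercised via layer
    n, h, w, c = dy.shape
    k = W.shape[0]
    for m in range(n):
        for r in range(h):
            for s in range(w):
                for i in range(k):
                    for j in range(k):
                        for ch in range(c):
                            g = dy[m, r, s, ch]
                            dW[i, j, ch] += xp[m, r + i, s + j, ch] * g
                            dxp[m, r + i, s + j, ch] += W[i, j, ch] * g


class DepthwiseConv2D:
    """Per-channel same-padded 2-D convolution (no cross-channel mixing);
    weights (k, k, C).  The inner loops are numba-compiled: a depthwise
    kernel at full input resolution is otherwise memory-bound in numpy."""

    def __init__(self, ch: int, k: int, rng: np.random.Generator,
                 pad_mode: str = "zeros", name: str = "dwconv") -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k, self.pad_mode = k, pad_mode
        self.W = Param(_he_normal(rng, (k, k, ch), k * k), f"{name}.W")
        self.b = Param(np.zeros(ch, dtype=np.float32), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.k // 2
        xp = np.ascontiguousarray(_pad2d(x, p, self.pad_mode))
        y = np.zeros_like(x)
        _dw_forward(xp, self.W.val, y)
        self._xp = xp
        return y + self.b.val

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = self._xp
        dxp = np.zeros_like(xp)
        dy = np.ascontiguousarray(dy)
        _dw_backward(xp, self.W.val, dy, self.W.grad, dxp)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        self._xp = None
        return _fold2d(dxp, p, self.pad_mode)


class BatchNorm:
    """Batch normalisation over all axes except the trailing channel axis.

    ``ndim=4`` normalises (N, H, W, C) per channel; ``ndim=2`` normalises
    (N, F) per feature.  Keeps running statistics for inference.
    """

    def __init__(self, ch: int, ndim: int = 4, momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "bn") -> None:
        self.ndim, self.momentum, self.eps = ndim, momentum, eps
        self.gamma = Param(np.ones(ch, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(ch, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean) / std
        self._xhat, self._std, self._axes = xhat, std, axes
        self._training = training
        return self.gamma.val * xhat + self.beta.val

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = self._axes
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not self._training:
            return (dy * self.gamma.val / std).astype(np.float32)
        dxhat = dy * self.gamma.val
        dx = (dxhat
              - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
              ) / std
        self._xhat = None
        return dx.astype(np.float32)


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(0.0))


class LeakyReLU:
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = np.float32(slope)

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class Dropout:
    """Inverted dropout; identity at inference.  ``rng`` is reseeded by the
    training loop so runs with the same seed are bit-identical."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32)
                      < keep) / np.float32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool2x2Ceil:
    """2x2 max-pooling, stride 2, ceil mode (77 -> 39, 35 -> 18)."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = -(-h // 2), -(-w // 2)
        xp = np.full((n, h2 * 2, w2 * 2, c), -np.inf, dtype=np.float32)
        xp[:, :h, :w, :] = x
        xw = xp.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xw = xw.reshape(n, h2, w2, c, 4)
        self._idx = xw.argmax(axis=-1)
        self._inshape = (n, h, w, c)
        return xw.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._inshape
        h2, w2 = -(-h // 2), -(-w // 2)
        dxw = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(dxw, self._idx[..., None], dy[..., None], axis=-1)
        dxp = dxw.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dxp = dxp.reshape(n, h2 * 2, w2 * 2, c)
        return np.ascontiguousarray(dxp[:, :h, :w, :])


class Flatten:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 name: str = "dense") -> None:
        self.W = Param(_he_normal(rng, (in_f, out_f), in_f), f"{name}.W")
        self.b = Param(np.zeros(out_f, dtype=np.float32), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.val + self.b.val

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.W.val.T


# ---------------------------------------------------------------------------
# loss and optimiser
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy for integer labels; returns (loss, dlogits, probs)."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(np.float32), probs


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.val) for p in self.params]
        self.v = [np.zeros_like(p.val) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
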