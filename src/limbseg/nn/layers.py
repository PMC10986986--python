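"""Minimal CPU neural-network layers with explicit backpropagation.

All tensors are float32 numpy arrays in NCHW layout.  Convolutions are
stride-1 same-padding correlations realised as im2col + GEMM; the input
gradient of a convolution is itself a same-padding correlation with the
spatially flipped, channel-transposed kernel, so forward and backward
share one primitive.  Each layer caches what its backward pass needs and
exposes its trainable tensors as :class:`Param` objects (value + gradient
accumulator) for the Adam optimiser.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*k*k) patches for stride-1 same-pad correlation."""
    b, c, h, w = x.shape
    if k == 1:
        return x.transpose(0, 2, 3, 1).reshape(b * h * w, c)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


class Conv2d:
    """k x k stride-1 same-padding convolution (k = 1 or 3)."""

    def __init__(self, c_in: int, c_out: int, k: int, bias: bool, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.W = Param(w)  # stored flat: (C_out, C_in*k*k)
        self.b = Param(np.zeros(c_out)) if bias else None
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if train else None
        self._in_shape = x.shape
        y = cols @ self.W.v.T
        if self.b is not None:
            y += self.b.v
        return y.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.W.g += dyf.T @ self._cols
        if self.b is not None:
            self.b.g += dyf.sum(axis=0)
        k = self.k
        w4 = self.W.v.reshape(self.c_out, self.c_in, k, k)
        w_flip = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * k * k)
        dcols = _im2col(dy, k)
        dx = dcols @ w_flip.T
        return dx.reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)


class ConvTranspose2x2:
    """2x2 stride-2 transposed convolution (learned up-sampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out * 4))
        self.W = Param(w)
        self.b = Param(np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        self._x = x if train else None
        self._in_shape = x.shape
        xf = x.transpose(0, 2, 3, 1).reshape(-1, c)
        y = xf @ self.W.v  # (B*H*W, C_out*4)
        y = y.reshape(b, h, w, self.c_out, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        return (y.reshape(b, self.c_out, 2 * h, 2 * w) + self.b.v[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyr = dy.reshape(b, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        dyf = dyr.reshape(-1, self.c_out * 4)
        xf = self._x.transpose(0, 2, 3, 1).reshape(-1, self.c_in)
        self.W.g += xf.T @ dyf
        self.b.g += dy.sum(axis=(0, 2, 3))
        dx = dyf @ self.W.v.T
        return dx.reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * istd[None, :, None, None]
        if train:
            self._xhat, self._istd = xhat, istd
        return (self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dy_sum = dy.sum(axis=(0, 2, 3))
        dyxhat_sum = (dy * xhat).sum(axis=(0, 2, 3))
        self.gamma.g += dyxhat_sum
        self.beta.g += dy_sum
        coef = (self.gamma.v * istd / n)[None, :, None, None]
        return (coef * (n * dy - dy_sum[None, :, None, None] - xhat * dyxhat_sum[None, :, None, None])).astype(np.float32)


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2x2:
    """2x2 stride-2 max pooling; even spatial sizes required."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        if train:
            self._idx, self._in_shape = idx, x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h, w
        )


class NearestUpsample2:
    """Parameter-free nearest-neighbour x2 up-sampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h2, w2 = dy.shape
        return dy.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Linear:
    def __init__(self, n_in: int, n_out: int, bias: bool, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.W = Param(rng.uniform(-scale, scale, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out)) if bias else None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        y = x @ self.W.v.T
        if self.b is not None:
            y += self.b.v
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += dy.T @ self._x
        if self.b is not None:
            self.b.g += dy.sum(axis=0)
        return (dy @ self.W.v).astype(np.float32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of an NCHW tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with the canonical published defaults (0.9, 0.999, 1e-8)."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.vv = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.vv):
            m *= b1
            m += (1 - b1) * p.g
            v *= b2
            v += (1 - b2) * p.g**2
            p.v -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
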