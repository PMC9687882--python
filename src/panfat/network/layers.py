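"""Minimal CNN layers in numpy with manual backpropagation.

Everything operates on float32 arrays of shape (B, C, H, W). Convolutions use
im2col + BLAS matmul; each layer caches what its backward pass needs. This is
deliberately small: just the pieces a 2-D encoder-decoder segmenter needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list  # list of (name, array) exposed for the optimizer

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k 'same' convolution, stride 1, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def _im2col(self, x):
        """(B, C, H, W) -> (B, C*k*k, H*W) via k*k contiguous slice copies."""
        b, c, h, w = x.shape
        k = self.k
        if k == 1:
            return x.reshape(b, c, h * w)
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = np.empty((b, c, k * k, h * w), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                cols[:, :, di * k + dj, :] = xp[:, :, di:di + h, dj:dj + w].reshape(b, c, h * w)
        return cols.reshape(b, c * k * k, h * w)

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        cols = self._im2col(np.ascontiguousarray(x, dtype=np.float32))
        out = np.matmul(self.w, cols)  # (B, out_ch, H*W)
        out += self.b[:, None]
        if train:
            self._cache = (cols, (b, c, h, w))
        return out.reshape(b, self.out_ch, h, w)

    def backward(self, dout):
        cols, (b, c, h, w) = self._cache
        k = self.k
        dflat = np.ascontiguousarray(dout, dtype=np.float32).reshape(b, self.out_ch, h * w)
        # (B, out_ch, HW) x (B, HW, C*k*k) summed over batch
        self.dw[...] = np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.db[...] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, dflat)  # (B, C*k*k, HW)
        self._cache = None
        if k == 1:
            return dcols.reshape(b, c, h, w)
        pad = k // 2
        dcols = dcols.reshape(b, c, k * k, h, w)
        dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, di * k + dj]
        return dxp[:, :, pad:pad + h, pad:pad + w]


class ReLU(Layer):
    params: list = []

    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties break toward the first maximum."""

    params: list = []

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x.reshape(b, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (b, c, h, w))
        return out

    def backward(self, dout):
        idx, (b, c, h, w) = self._cache
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((b, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        self._cache = None
        return dx


class UpsampleNearest2(Layer):
    """Nearest-neighbor 2x upsampling; backward sums each 2x2 block."""

    params: list = []

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam over an explicit (param, grad) list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def soft_dice_loss(p: np.ndarray, y: np.ndarray, eps: float = 1.0):
    """Per-sample soft Dice loss and its gradient w.r.t. p.

    ``L = 1 - (2 sum(p y) + eps) / (sum(p) + sum(y) + eps)`` averaged over the
    batch; p and y are (B, H, W).
    """
    b = p.shape[0]
    axes = (1, 2)
    inter = (p * y).sum(axis=axes)
    denom = p.sum(axes) + y.sum(axes) + eps
    num = 2.0 * inter + eps
    loss = float(np.mean(1.0 - num / denom))
    dp = -(2.0 * y * denom[:, None, None] - num[:, None, None]) / denom[:, None, None] ** 2
    return loss, (dp / b).astype(np.float32)


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7):
    """Pixel-mean binary cross-entropy and gradient w.r.t. p."""
    pc = np.clip(p, eps, 1 - eps)
    loss = float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))
    dp = ((pc - y) / (pc * (1 - pc))) / p.size
    return loss, dp.astype(np.float32)
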