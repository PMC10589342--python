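"""Building-block layers with explicit forward/backward passes.

Everything runs on float32 numpy arrays in channels-first layout
(B, C, D, H, W).  The convolution is evaluated in the Fourier domain
(batched real FFTs over the spatial axes), which avoids the 27x im2col
lowering that dominates a direct GEMM formulation on one CPU core; the
weight gradient is a batched FFT cross-correlation read off at the k^3
kernel lags.  A windowed einsum (``_conv_reference``) is the direct-space
reference implementation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sp_fft

__all__ = ["Layer", "Conv3d", "BatchNorm3d", "ReLU", "LeakyReLU", "MaxPool3d", "Linear"]


class Layer:
    """Base layer: parameters exposed as (name, param, grad) triples."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _conv_reference(x: np.ndarray, W: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Windowed-einsum 3D correlation (numpy fallback and test reference)."""
    k = W.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    out = np.einsum("bcdhwxyz,ocxyz->bodhw", win, W, optimize=True)
    return (out + bias[None, :, None, None, None]).astype(np.float32)


class Conv3d(Layer):
    """Same-padding 3D convolution (odd kernel), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, kernel, kernel, kernel)
                            ).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xh: np.ndarray | None = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _fft_shape(self, spatial) -> tuple[int, ...]:
        return tuple(sp_fft.next_fast_len(s + self.k - 1) for s in spatial)

    def _conv_from_spectrum(self, xh, W, bias, spatial, fs) -> np.ndarray:
        """Same-padding correlation given the input spectrum."""
        # flipping the kernel turns the FFT convolution into a correlation
        wh = sp_fft.rfftn(W[:, :, ::-1, ::-1, ::-1].astype(np.float32),
                          fs, axes=(2, 3, 4))
        O = W.shape[0]
        yh = np.empty((xh.shape[0], O) + xh.shape[2:], dtype=xh.dtype)
        for o in range(O):
            np.sum(xh * wh[o], axis=1, out=yh[:, o])
        y = sp_fft.irfftn(yh, fs, axes=(2, 3, 4))
        p = self.k // 2
        d, h, w = spatial
        crop = y[:, :, p:p + d, p:p + h, p:p + w]
        return (crop + bias[None, :, None, None, None]).astype(np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"conv expected {self.in_ch} channels, got {x.shape[1]}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        spatial = x.shape[2:]
        fs = self._fft_shape(spatial)
        xh = sp_fft.rfftn(x, fs, axes=(2, 3, 4))
        if train:
            self._xh, self._spatial, self._fs = xh, spatial, fs
        return self._conv_from_spectrum(xh, self.W, self.b, spatial, fs)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.db[...] = dy.sum(axis=(0, 2, 3, 4))
        fs = self._fs
        dyh = sp_fft.rfftn(dy, fs, axes=(2, 3, 4))
        # weight gradient: cross-correlation of input and upstream gradient,
        # read off at the kernel lags (kd - p, kh - p, kw - p)
        gh = np.empty((self.out_ch, self.in_ch) + dyh.shape[2:],
                      dtype=dyh.dtype)
        xh_conj = np.conj(self._xh)
        for o in range(self.out_ch):
            np.sum(xh_conj * dyh[:, o:o + 1], axis=0, out=gh[o])
        g = sp_fft.irfftn(gh, fs, axes=(2, 3, 4))
        # ifft(conj(X) * DY)[lam] = sum_d x[d - lam] dy[d], so the kernel
        # offset kd - p is read at lag p - kd
        p = self.k // 2
        lags = [p - np.arange(self.k) for _ in range(3)]
        ix = np.ix_(*[lag % n for lag, n in zip(lags, fs)])
        self.dW[...] = g[:, :, ix[0], ix[1], ix[2]]
        self._xh = None
        # input gradient: full correlation with flipped, transposed kernel
        wback = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        return self._conv_from_spectrum(
            dyh, wback, np.zeros(self.in_ch, dtype=np.float32),
            self._spatial, fs)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (B, D, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma),
                ("beta", self.beta, self.dbeta)]

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v[None, :, None, None, None]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - self._bc(mean)) * self._bc(inv)
        if train:
            self._cache = (xhat, inv)
        return self._bc(self.gamma) * xhat + self._bc(self.beta)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        term = (dy - self._bc(self.dbeta) / m
                - xhat * self._bc(self.dgamma) / m)
        return self._bc(self.gamma * inv) * term


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LeakyReLU(Layer):
    """Leaky rectifier: units keep a small gradient when negative, so a
    layer cannot get permanently stuck in an all-dead state."""

    def __init__(self, slope: float = 0.01):
        self.slope = np.float32(slope)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool3d(Layer):
    """Non-overlapping 2x2x2 max pooling (kernel = stride = 2)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2x2 pooling")
        r = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5, 7))
        if train:
            self._mask = r == out[:, :, :, None, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, d, h, w = self._shape
        up = np.zeros((b, c, d // 2, 2, h // 2, 2, w // 2, 2), dtype=dy.dtype)
        up += dy[:, :, :, None, :, None, :, None]
        # ties share the gradient equally (deterministic)
        counts = self._mask.sum(axis=(3, 5, 7), keepdims=True)
        up = np.where(self._mask, up / counts, 0.0)
        return up.reshape(b, c, d, h, w).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Adam:
    """Adam optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (_, p, g) in enumerate(self.params):
            self.m[i] += (1.0 - self.b1) * (g - self.m[i])
            self.v[i] += (1.0 - self.b2) * (g * g - self.v[i])
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
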