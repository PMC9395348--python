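"""Differentiable operations for small convolutional networks.

Every op implements ``forward(*inputs, train=False) -> (output, cache)`` and
``backward(d_output, cache) -> tuple_of_input_grads``.  Parameter gradients
are accumulated in-place on :class:`Param` objects, so callers must zero them
between steps (the optimizer does this).

Tensors are ``float32`` arrays in NCHW layout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Op",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "ReLU6",
    "Sigmoid",
    "MaxPool2",
    "Upsample",
    "Concat",
]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Op:
    def params(self) -> list[Param]:
        return []

    def forward(self, *inputs, train: bool = False):  # pragma: no cover
        raise NotImplementedError

    def backward(self, d_out, cache):  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, out_h: int, out_w: int) -> np.ndarray:
    """Stack k x k shifted views of the padded input: (N, C*k*k, H*W)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, out_h, out_w), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + out_h, j : j + out_w]
    return cols.reshape(n, c * k * k, out_h * out_w)


class Conv2D(Op):
    """Same-padded 2-D convolution (square kernel, stride 1) via im2col."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU family
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        self.w = Param(rng.normal(0.0, scale, size=(c_out, fan_in)))
        self.b = Param(np.zeros(c_out)) if bias else None

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.ksize // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.ksize, h, w)
        y = np.matmul(self.w.data, cols)  # (N, c_out, H*W)
        if self.b is not None:
            y += self.b.data[:, None]
        return y.reshape(n, self.c_out, h, w), (cols, (n, c, h, w))

    def backward(self, d_out, cache):
        cols, (n, c, h, w) = cache
        k, p = self.ksize, self.ksize // 2
        dy = d_out.reshape(n, self.c_out, h * w)
        self.w.grad += np.tensordot(dy, cols, axes=([0, 2], [0, 2]))
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2))
        dcols = np.matmul(self.w.data.T, dy).reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=d_out.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
        return (dx,)


class BatchNorm2D(Op):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = False):
        g = self.gamma.data[:, None, None]
        b = self.beta.data[:, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[:, None, None]) * inv_std[:, None, None]
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            return g * xhat + b, (xhat, inv_std, True)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[:, None, None]) * inv_std[:, None, None]
        return g * xhat + b, (xhat, inv_std, False)

    def backward(self, d_out, cache):
        xhat, inv_std, was_train = cache
        g = self.gamma.data[:, None, None]
        if not was_train:
            # running stats are constants in eval mode, so the map is affine
            self.gamma.grad += (d_out * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += d_out.sum(axis=(0, 2, 3))
            return (d_out * g * inv_std[:, None, None],)
        m = d_out.shape[0] * d_out.shape[2] * d_out.shape[3]
        self.gamma.grad += (d_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += d_out.sum(axis=(0, 2, 3))
        dxhat = d_out * g
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        dx = (inv_std[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return (dx,)


class ReLU(Op):
    def forward(self, x, train: bool = False):
        mask = x > 0
        return x * mask, mask

    def backward(self, d_out, cache):
        return (d_out * cache,)


class ReLU6(Op):
    """min(max(0, x), 6) — the bottleneck activation."""

    def forward(self, x, train: bool = False):
        mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0), mask

    def backward(self, d_out, cache):
        return (d_out * cache,)


class Sigmoid(Op):
    def forward(self, x, train: bool = False):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, d_out, cache):
        y = cache
        return (d_out * y * (1.0 - y),)


class MaxPool2(Op):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return y, (idx, (n, c, h, w))

    def backward(self, d_out, cache):
        idx, (n, c, h, w) = cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=d_out.dtype)
        np.put_along_axis(dxr, idx[..., None], d_out[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(n, c, h, w),)


def _interp_matrix(n_in: int, scale: int, mode: str) -> np.ndarray:
    """1-D upsampling operator (n_in*scale, n_in) for nearest/bilinear."""
    n_out = n_in * scale
    u = np.zeros((n_out, n_in), dtype=np.float32)
    if mode == "nearest":
        for i in range(n_out):
            u[i, i // scale] = 1.0
    elif mode == "bilinear":
        for i in range(n_out):
            src = (i + 0.5) / scale - 0.5
            lo = int(np.floor(src))
            t = src - lo
            lo_c = min(max(lo, 0), n_in - 1)
            hi_c = min(max(lo + 1, 0), n_in - 1)
            u[i, lo_c] += 1.0 - t
            u[i, hi_c] += t
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return u


class Upsample(Op):
    """Integer-factor 2-D upsampling as a separable linear map.

    The forward pass is ``U_h @ x @ U_w.T`` per channel, which makes the
    backward pass the exact transpose — no scatter logic required.
    """

    def __init__(self, scale: int, mode: str = "nearest"):
        if scale < 1 or int(scale) != scale:
            raise ValueError("scale must be a positive integer")
        self.scale = int(scale)
        self.mode = mode
        self._cache_mats: dict[tuple[int, int], np.ndarray] = {}

    def _mat(self, n_in: int) -> np.ndarray:
        key = (n_in, self.scale)
        if key not in self._cache_mats:
            self._cache_mats[key] = _interp_matrix(n_in, self.scale, self.mode)
        return self._cache_mats[key]

    def forward(self, x, train: bool = False):
        h, w = x.shape[2], x.shape[3]
        uh, uw = self._mat(h), self._mat(w)
        y = np.matmul(np.matmul(uh, x), uw.T)
        return y, (h, w)

    def backward(self, d_out, cache):
        h, w = cache
        uh, uw = self._mat(h), self._mat(w)
        return (np.matmul(np.matmul(uh.T, d_out), uw),)


class Concat(Op):
    """Channel-axis concatenation of two feature maps."""

    def forward(self, a, b, train: bool = False):
        if a.shape[2:] != b.shape[2:]:
            raise ValueError("spatial dims differ between concat inputs")
        return np.concatenate([a, b], axis=1), (a.shape[1],)

    def backward(self, d_out, cache):
        (ca,) = cache
        return d_out[:, :ca], d_out[:, ca:]
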