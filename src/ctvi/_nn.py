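"""Minimal 3-D convolutional network engine (NumPy + BLAS).

Implements exactly the layer set the ventilation U-Net needs — 3×3×3
convolution (stride 1, pad 1), 2×2×2 max-pooling, 2×2×2 stride-2
transposed convolution, leaky-ReLU/ReLU, Bernoulli dropout — with manual
reverse-mode gradients and an Adam optimizer.  Convolutions are lowered
to GEMMs through ``sliding_window_view`` (im2col), which keeps desk-scale
volumes (≤ 64³) fast on a single CPU core.

Tensors are single-sample ``(C, D, H, W)`` float32 arrays; batches are
handled by the caller by accumulating gradients over samples.  Dropout is
"inverted" (mask scaled by 1/(1−p) at sampling time), so evaluation-mode
passes need no rescaling — the same convention the original dropout
formulation induces at test time and the one modern frameworks use, which
is what Monte-Carlo dropout sampling relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "Conv1x1",
    "TransposedConv3d",
    "MaxPool3d",
    "LeakyReLU",
    "ReLU",
    "Dropout",
    "Adam",
    "glorot_uniform",
]

_DT = np.float32


def glorot_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DT)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) → (C·27, D·H·W) patch matrix for a 3³ kernel, pad 1.

    Row ``c*27 + k`` holds the voxel at kernel offset ``k`` (z-major) of
    channel ``c`` — matching the flattening of a ``(C_out, C_in, 3, 3, 3)``
    kernel, so convolution is a single GEMM.  Built from 27 slab copies,
    which beats any transpose of a sliding-window view.
    """
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((c, 27, d, h, w), dtype=x.dtype)
    k = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                cols[:, k] = xp[:, dz : dz + d, dy : dy + h, dx : dx + w]
                k += 1
    return cols.reshape(c * 27, d * h * w)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv3d(Layer):
    """3×3×3 convolution, stride 1, zero-padding 1 (shape-preserving)."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.cin, self.cout = cin, cout
        w = glorot_uniform((cout, cin, 3, 3, 3), cin * 27, cout * 27, rng)
        b = np.zeros(cout, dtype=_DT)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.regularized = [True, False]  # L2 on kernels only

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape[1:]
        cols = _im2col(x)
        self._cols = cols if training else None
        w, b = self.params
        y = w.reshape(self.cout, -1) @ cols
        d, h, wd = self._shape
        return y.reshape(self.cout, d, h, wd) + b[:, None, None, None]

    def backward(self, gy):
        w, _ = self.params
        d, h, wd = self._shape
        g = gy.reshape(self.cout, -1)
        self.grads[0] += (g @ self._cols.T).reshape(w.shape)
        self.grads[1] += g.sum(axis=1)
        # dx = full correlation of gy with the flipped, channel-swapped kernel
        wflip = np.ascontiguousarray(
            w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        ).reshape(self.cin, -1)
        dx = wflip @ _im2col(gy)
        self._cols = None
        return dx.reshape(self.cin, d, h, wd)


class Conv1x1(Layer):
    """1×1×1 convolution (per-voxel linear map across channels)."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.cin, self.cout = cin, cout
        w = glorot_uniform((cout, cin), cin, cout, rng)
        b = np.zeros(cout, dtype=_DT)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.regularized = [True, False]

    def forward(self, x, training=False, rng=None):
        self._x = x
        w, b = self.params
        y = np.tensordot(w, x, axes=([1], [0]))
        return y + b[:, None, None, None]

    def backward(self, gy):
        self.grads[0] += np.tensordot(gy, self._x, axes=([1, 2, 3], [1, 2, 3]))
        self.grads[1] += gy.sum(axis=(1, 2, 3))
        return np.tensordot(self.params[0].T, gy, axes=([1], [0]))


class TransposedConv3d(Layer):
    """2×2×2 transposed convolution with stride 2 (doubles each spatial axis)."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.cin, self.cout = cin, cout
        w = glorot_uniform((cin, cout, 2, 2, 2), cin, cout * 8, rng)
        b = np.zeros(cout, dtype=_DT)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.regularized = [True, False]

    def forward(self, x, training=False, rng=None):
        self._x = x
        w, b = self.params
        d, h, wd = x.shape[1:]
        # (cout,2,2,2, d,h,w) → interleave offsets into the upsampled grid
        y = np.tensordot(w, x, axes=([0], [0]))
        y = y.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.cout, 2 * d, 2 * h, 2 * wd)
        return y + b[:, None, None, None]

    def backward(self, gy):
        w, _ = self.params
        cout = self.cout
        d2, h2, w2 = gy.shape[1:]
        g = gy.reshape(cout, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        # g: (cout, 2,2,2, d,h,w)
        self.grads[0] += np.tensordot(self._x, g, axes=([1, 2, 3], [4, 5, 6]))
        self.grads[1] += gy.sum(axis=(1, 2, 3))
        return np.tensordot(w, g, axes=([1, 2, 3, 4], [0, 1, 2, 3]))


class MaxPool3d(Layer):
    """2×2×2 max pooling with stride 2; ties route the gradient to the first max."""

    def forward(self, x, training=False, rng=None):
        c, d, h, w = x.shape
        blocks = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, (d // 2) * (h // 2) * (w // 2), 8)
        )
        self._argmax = blocks.argmax(axis=2)
        self._shape = x.shape
        y = np.take_along_axis(blocks, self._argmax[..., None], axis=2)[..., 0]
        return y.reshape(c, d // 2, h // 2, w // 2)

    def backward(self, gy):
        c, d, h, w = self._shape
        nb = (d // 2) * (h // 2) * (w // 2)
        gb = np.zeros((c, nb, 8), dtype=gy.dtype)
        np.put_along_axis(gb, self._argmax[..., None], gy.reshape(c, nb, 1), axis=2)
        return (
            gb.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.30):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, gy):
        return np.where(self._neg, self.alpha * gy, gy)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._neg = x < 0
        return np.where(self._neg, 0.0, x).astype(x.dtype, copy=False)

    def backward(self, gy):
        return np.where(self._neg, 0.0, gy).astype(gy.dtype, copy=False)


class Dropout(Layer):
    """Inverted Bernoulli dropout; active only when ``training`` is True."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / _DT(keep)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=5e-5, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
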