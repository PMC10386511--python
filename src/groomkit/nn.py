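"""Minimal 3D convolutional neural-network layers on numpy.

All layers operate on float32 tensors in ``(N, C, T, H, W)`` layout
(batch, channels, time, height, width). Each layer caches what it needs
during ``forward`` and returns input gradients from ``backward``;
parameters and their gradients are exposed through ``params()`` so an
optimizer can update them in place.

The 3D convolution is evaluated as a sum over the 27 kernel offsets,
each offset reducing to a single BLAS matmul of shape
``(C_out, C_in) @ (N, C_in, T*H*W)``. This keeps memory bounded (one
shifted copy of the input at a time) while staying fast enough for the
desk-scale networks used here.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Conv3d",
    "ReLU",
    "MaxPool3d",
    "AdaptiveAvgPool3d",
    "Linear",
    "Dropout",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


class Layer:
    """Base class: parameterless identity; subclasses override."""

    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """3x3x3 (by default) 3D convolution, stride 1, zero padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, pad: int = 1):
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.pad = int(kernel), int(pad)
        fan_in = c_in * kernel ** 3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel, kernel))
                  * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._offsets = list(itertools.product(range(kernel), repeat=3))

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        n, c, t, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp, self._in_shape = xp, x.shape
        length = t * h * w
        out = np.zeros((n, self.c_out, length),
                       dtype=np.result_type(x.dtype, np.float32))
        out += self.b[:, None]
        for dt, dh, dw in self._offsets:
            sub = xp[:, :, dt:dt + t, dh:dh + h, dw:dw + w].reshape(n, c, length)
            out += self.w[:, :, dt, dh, dw] @ sub
        return out.reshape(n, self.c_out, t, h, w)

    def backward(self, dy, need_dx: bool = True):
        n, c, t, h, w = self._in_shape
        length = t * h * w
        dyf = np.ascontiguousarray(dy.reshape(n, self.c_out, length))
        self.db[:] = dyf.sum(axis=(0, 2))
        xp = self._xp
        dxp = np.zeros_like(xp) if need_dx else None
        for dt, dh, dw in self._offsets:
            sub = xp[:, :, dt:dt + t, dh:dh + h, dw:dw + w].reshape(n, c, length)
            self.dw[:, :, dt, dh, dw] = np.einsum(
                "nol,ncl->oc", dyf, sub, optimize=True)
            if need_dx:
                grad = (self.w[:, :, dt, dh, dw].T @ dyf).reshape(n, c, t, h, w)
                dxp[:, :, dt:dt + t, dh:dh + h, dw:dw + w] += grad
        p = self.pad
        self._xp = None
        if not need_dx:
            return None
        return dxp[:, :, p:p + t, p:p + h, p:p + w]


class ReLU(Layer):
    """Rectifier; a nonzero ``slope`` makes it leaky, which keeps very
    narrow layers trainable (a dead unit in a 2-channel layer silences
    the whole network)."""

    def __init__(self, slope: float = 0.0):
        self.slope = float(slope)

    def forward(self, x, train=False):
        self._mask = x > 0
        if self.slope == 0.0:
            return np.where(self._mask, x, 0).astype(x.dtype, copy=False)
        return np.where(self._mask, x, self.slope * x).astype(x.dtype,
                                                              copy=False)

    def backward(self, dy):
        if self.slope == 0.0:
            return np.where(self._mask, dy, 0).astype(dy.dtype, copy=False)
        return np.where(self._mask, dy, self.slope * dy).astype(dy.dtype,
                                                                copy=False)


class MaxPool3d(Layer):
    """Non-overlapping max pooling (kernel == stride), ceil mode.

    Odd extents are padded with -inf so the trailing partial window is
    kept, matching the ceil-mode pooling used by the reference C3D
    topology (112 -> 56 -> 28 -> 14 -> 7 -> 4).
    """

    def __init__(self, kernel=(2, 2, 2)):
        self.kernel = tuple(int(k) for k in kernel)

    def forward(self, x, train=False):
        n, c, t, h, w = x.shape
        kt, kh, kw = self.kernel
        pt, ph, pw = (-t) % kt, (-h) % kh, (-w) % kw
        self._in_shape = x.shape
        self._padded = (t + pt, h + ph, w + pw)
        if pt or ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, pt), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        tb, hb, wb = (t + pt) // kt, (h + ph) // kh, (w + pw) // kw
        blocks = (x.reshape(n, c, tb, kt, hb, kh, wb, kw)
                  .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                  .reshape(n, c, tb, hb, wb, kt * kh * kw))
        self._argmax = blocks.argmax(axis=-1)
        return np.take_along_axis(
            blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, t, h, w = self._in_shape
        kt, kh, kw = self.kernel
        tp, hp, wp = self._padded
        tb, hb, wb = tp // kt, hp // kh, wp // kw
        blocks = np.zeros((n, c, tb, hb, wb, kt * kh * kw),
                          dtype=dy.dtype)
        np.put_along_axis(blocks, self._argmax[..., None], dy[..., None],
                          axis=-1)
        dxp = (blocks.reshape(n, c, tb, hb, wb, kt, kh, kw)
               .transpose(0, 1, 2, 5, 3, 6, 4, 7)
               .reshape(n, c, tp, hp, wp))
        return np.ascontiguousarray(dxp[:, :, :t, :h, :w])


class AdaptiveAvgPool3d(Layer):
    """Average pooling to a fixed output extent with torch-style bins."""

    def __init__(self, out_size=(4, 7, 7)):
        self.out_size = tuple(int(s) for s in out_size)

    @staticmethod
    def _edges(n_in, n_out):
        starts = [(i * n_in) // n_out for i in range(n_out)]
        ends = [-(-((i + 1) * n_in) // n_out) for i in range(n_out)]
        return list(zip(starts, ends))

    def forward(self, x, train=False):
        n, c = x.shape[:2]
        self._in_shape = x.shape
        ot, oh, ow = self.out_size
        et = self._edges(x.shape[2], ot)
        eh = self._edges(x.shape[3], oh)
        ew = self._edges(x.shape[4], ow)
        self._bins = (et, eh, ew)
        out = np.empty((n, c, ot, oh, ow), dtype=x.dtype)
        for i, (t0, t1) in enumerate(et):
            for j, (h0, h1) in enumerate(eh):
                for k, (w0, w1) in enumerate(ew):
                    out[:, :, i, j, k] = x[:, :, t0:t1, h0:h1, w0:w1].mean(
                        axis=(2, 3, 4))
        return out

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        et, eh, ew = self._bins
        for i, (t0, t1) in enumerate(et):
            for j, (h0, h1) in enumerate(eh):
                for k, (w0, w1) in enumerate(ew):
                    cnt = (t1 - t0) * (h1 - h0) * (w1 - w0)
                    dx[:, :, t0:t1, h0:h1, w0:w1] += (
                        dy[:, :, i, j, k] / cnt)[:, :, None, None, None]
        return dx


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw[:] = dy.T @ self._x
        self.db[:] = dy.sum(axis=0)
        self._x = None
        return dy @ self.w


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = float(p)
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(
            np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy loss. Returns (loss, probs, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), probs, dlogits.astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, layers, lr: float, momentum: float = 0.9):
        self.layers = layers
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._vel = [np.zeros_like(p) for layer in layers
                     for p, _ in layer.params()]

    def step(self):
        i = 0
        for layer in self.layers:
            for p, g in layer.params():
                v = self._vel[i]
                v *= self.momentum
                v -= self.lr * g
                p += v
                i += 1
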