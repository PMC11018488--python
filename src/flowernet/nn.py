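"""Minimal CNN layer engine on numpy.

Implements exactly the primitives the counting network needs — 2-D
convolution (im2col + BLAS matmul), 2×2 max pooling with ceil-mode shape
handling, nearest-neighbour ×2 upsampling, ReLU/sigmoid, and Adam — each
with an explicit, cached backward pass.  Arrays are NCHW float32
throughout.  There is no autograd: networks wire forward and backward by
hand, which keeps the data flow auditable and the per-step overhead low
enough for single-CPU training.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base class: subclasses cache what backward needs during forward."""

    def params(self) -> list[tuple[str, Param]]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (C*kh*kw, N*ho*wo) patch matrix (kh*kw slice copies)."""
    n, c = xp.shape[:2]
    cols = np.empty((c, kh, kw, n, ho, wo), dtype=F32)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[:, :, i:i + ho * stride:stride,
                               j:j + wo * stride:stride].transpose(1, 0, 2, 3)
    return cols.reshape(c * kh * kw, n * ho * wo)


class Conv2d(Layer):
    """2-D convolution, zero padding, square kernel, optional stride."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Param(np.zeros((cout, cin, k, k), dtype=F32))
        self.bias = Param(np.zeros(cout, dtype=F32))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        s, k, p = self.stride, self.k, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for k={k}, stride={s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, k, s, ho, wo)
        y = self.weight.value.reshape(self.cout, -1) @ cols
        y += self.bias.value[:, None]
        self._cols, self._xshape = cols, (n, c, h, w, ho, wo)
        return np.ascontiguousarray(
            y.reshape(self.cout, n, ho, wo).transpose(1, 0, 2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo = self._xshape
        s, k, p = self.stride, self.k, self.pad
        dy_r = dy.transpose(1, 0, 2, 3).reshape(self.cout, -1)
        self.weight.grad += (dy_r @ self._cols.T).reshape(self.weight.value.shape)
        self.bias.grad += dy_r.sum(axis=1)
        dcols = (self.weight.value.reshape(self.cout, -1).T @ dy_r)
        dcols = dcols.reshape(c, k, k, n, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += \
                    dcols[:, i, j].transpose(1, 0, 2, 3)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class MaxPool2(Layer):
    """2×2 max pooling, stride 2, ceil mode (odd edges padded with -inf)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        xp = x
        if ph or pw:
            xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                        constant_values=-np.inf)
        ho, wo = xp.shape[2] // 2, xp.shape[3] // 2
        xr = xp.reshape(n, c, ho, 2, wo, 2)
        y = xr.max(axis=(3, 5))
        # ties share the incoming gradient; deterministic and symmetric
        self._mask = (xr == y[:, :, :, None, :, None])
        self._shape = (n, c, h, w, ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo = self._shape
        dxr = self._mask * dy[:, :, :, None, :, None]
        dxp = dxr.reshape(n, c, ho * 2, wo * 2)
        return np.ascontiguousarray(dxp[:, :, :h, :w])


class NearestUp2(Layer):
    """Nearest-neighbour doubling; crops to a target size for odd shapes."""

    def forward(self, x: np.ndarray,
                target_hw: tuple[int, int] | None = None) -> np.ndarray:
        n, c, h, w = x.shape
        th, tw = target_hw if target_hw is not None else (2 * h, 2 * w)
        if not (2 * h - 1 <= th <= 2 * h and 2 * w - 1 <= tw <= 2 * w):
            raise ValueError(f"target {th}x{tw} not reachable from {h}x{w}")
        y = x.repeat(2, axis=2).repeat(2, axis=3)[:, :, :th, :tw]
        self._shape = (n, c, h, w, th, tw)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w, th, tw = self._shape
        dyp = dy
        if th < 2 * h or tw < 2 * w:
            dyp = np.pad(dy, ((0, 0), (0, 0), (0, 2 * h - th), (0, 2 * w - tw)))
        return dyp.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, dy, F32(0.0))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable split by sign
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Adam:
    """Adam over a flat parameter list (Kingma & Ba defaults)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
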