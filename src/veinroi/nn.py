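"""Compact NumPy neural-network toolkit with explicit backward passes.

All layers operate on float32 arrays in NCHW layout.  Each layer exposes
``forward(x, train=False)`` and ``backward(dout)``; trainable tensors are
:class:`Param` objects collected through ``params()`` and updated by
:class:`Adam`.  Convolutions are evaluated as a single im2col + GEMM so the
heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("v", "g", "name")

    def __init__(self, v: np.ndarray, name: str = "") -> None:
        self.v = np.ascontiguousarray(v, dtype=np.float32)
        self.g = np.zeros_like(self.v)
        self.name = name

    @property
    def size(self) -> int:
        return self.v.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolution

def _pad2d(x: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return x
    spec = ((0, 0), (0, 0), (p, p), (p, p))
    return np.pad(x, spec, mode="edge" if mode == "edge" else "constant")


def _unpad_grad(dxp: np.ndarray, p: int, mode: str) -> np.ndarray:
    """Adjoint of _pad2d: fold padded-border gradients back onto the edges."""
    if p == 0:
        return dxp
    if mode != "edge":
        return dxp[:, :, p:-p, p:-p]
    dx = dxp[:, :, p:-p, p:-p].copy()
    dx[:, :, 0, :] += dxp[:, :, :p, p:-p].sum(axis=2)
    dx[:, :, -1, :] += dxp[:, :, -p:, p:-p].sum(axis=2)
    dx[:, :, :, 0] += dxp[:, :, p:-p, :p].sum(axis=3)
    dx[:, :, :, -1] += dxp[:, :, p:-p, -p:].sum(axis=3)
    dx[:, :, 0, 0] += dxp[:, :, :p, :p].sum(axis=(2, 3))
    dx[:, :, 0, -1] += dxp[:, :, :p, -p:].sum(axis=(2, 3))
    dx[:, :, -1, 0] += dxp[:, :, -p:, :p].sum(axis=(2, 3))
    dx[:, :, -1, -1] += dxp[:, :, -p:, -p:].sum(axis=(2, 3))
    return dx


class Conv2d(Layer):
    """k x k convolution, 'same'-style padding (p = k // 2), arbitrary stride.

    pad_mode 'zeros' or 'edge' (replicate border, used by the stem).
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad_mode: str = "zeros", rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        self.pad_mode = pad_mode
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, (cout, cin, k, k)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._cache = None
        self.last_out_hw: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s = self.k, self.stride
        sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (C*k*k, N*Ho*Wo)
        n = xp.shape[0]
        cols = sw.transpose(1, 4, 5, 0, 2, 3).reshape(self.cin * k * k, n * ho * wo)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, _, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = _pad2d(x, p, self.pad_mode)
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, ho, wo)
        wmat = self.W.v.reshape(self.cout, -1)
        y = wmat @ cols + self.b.v[:, None]
        y = y.reshape(self.cout, n, ho, wo).transpose(1, 0, 2, 3)
        self.last_out_hw = (ho, wo)
        if train:
            self._cache = (cols, xp.shape, (n, h, w, ho, wo))
        return np.ascontiguousarray(y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, h, w, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dy = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(self.cout, -1)
        self.W.g += (dy @ cols.T).reshape(self.W.v.shape)
        self.b.g += dy.sum(axis=1)
        dcols = self.W.v.reshape(self.cout, -1).T @ dy
        dcols = dcols.reshape(self.cin, k, k, n, ho, wo)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += \
                    dcols[:, di, dj].transpose(1, 0, 2, 3)
        self._cache = None
        return _unpad_grad(dxp, p, self.pad_mode)

    def flops(self) -> int:
        ho, wo = self.last_out_hw
        return 2 * self.k * self.k * self.cin * self.cout * ho * wo


class ConvTranspose2d(Layer):
    """2x upsampling transposed convolution with a 2x2 kernel, stride 2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 name: str = "convT") -> None:
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, (cin, cout, 2, 2)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._cache = None
        self.last_out_hw: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, -1)
        y = np.empty((n, self.cout, 2 * h, 2 * w), dtype=np.float32)
        for di in range(2):
            for dj in range(2):
                blk = (self.W.v[:, :, di, dj].T @ xr).reshape(self.cout, n, h, w)
                y[:, :, di::2, dj::2] = blk.transpose(1, 0, 2, 3)
        y += self.b.v[None, :, None, None]
        self.last_out_hw = (2 * h, 2 * w)
        if train:
            self._cache = (xr, (n, c, h, w))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, (n, c, h, w) = self._cache
        dx = np.zeros((c, n * h * w), dtype=np.float32)
        for di in range(2):
            for dj in range(2):
                dyr = np.ascontiguousarray(
                    dout[:, :, di::2, dj::2].transpose(1, 0, 2, 3)).reshape(self.cout, -1)
                self.W.g[:, :, di, dj] += xr @ dyr.T
                dx += self.W.v[:, :, di, dj] @ dyr
        self.b.g += dout.sum(axis=(0, 2, 3))
        self._cache = None
        return dx.reshape(c, n, h, w).transpose(1, 0, 2, 3)

    def flops(self) -> int:
        ho, wo = self.last_out_hw
        return 2 * self.cin * self.cout * ho * wo


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.rm = np.zeros(c, dtype=np.float32)
        self.rv = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.rm = (1 - self.momentum) * self.rm + self.momentum * mu
            self.rv = (1 - self.momentum) * self.rv + self.momentum * var
        else:
            mu, var = self.rm, self.rv
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * istd[None, :, None, None]
        if train:
            self._cache = (xhat, istd)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, istd = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.g += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.v[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3)) / m
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3)) / m
        dx = (dxhat - t1[None, :, None, None] - xhat * t2[None, :, None, None]) \
            * istd[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dx = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


def _bilinear_matrix(h: int) -> np.ndarray:
    """Dense (2h, h) operator for 2x bilinear upsampling (half-pixel centers)."""
    A = np.zeros((2 * h, h), dtype=np.float32)
    for i in range(2 * h):
        src = (i + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), h - 1)
        i1c = min(max(i0 + 1, 0), h - 1)
        A[i, i0c] += 1.0 - t
        A[i, i1c] += t
    return A


class BilinearUp2(Layer):
    """2x bilinear upsampling as separable dense matrix products."""

    _cache_mats: dict[int, np.ndarray] = {}

    def __init__(self) -> None:
        self._shape = None

    @classmethod
    def _mat(cls, h: int) -> np.ndarray:
        if h not in cls._cache_mats:
            cls._cache_mats[h] = _bilinear_matrix(h)
        return cls._cache_mats[h]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        Ah, Aw = self._mat(h), self._mat(w)
        y = np.matmul(np.matmul(Ah, x), Aw.T)
        if train:
            self._shape = (h, w)
        return np.ascontiguousarray(y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._shape
        Ah, Aw = self._mat(h), self._mat(w)
        dx = np.matmul(np.matmul(Ah.T, dout), Aw)
        self._shape = None
        return np.ascontiguousarray(dx)


# ---------------------------------------------------------------------------
# optimizer / schedule

class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m *= self.b1
            m += (1 - self.b1) * p.g
            s *= self.b2
            s += (1 - self.b2) * p.g * p.g
            p.v -= self.lr * (m / bc1) / (np.sqrt(s / bc2) + self.eps)


class StepLR:
    """Multiply the optimizer learning rate by gamma every `step_every` epochs."""

    def __init__(self, opt: Adam, step_every: int, gamma: float = 0.5) -> None:
        self.opt = opt
        self.step_every = max(1, int(step_every))
        self.gamma = gamma
        self.base_lr = opt.lr

    def at_epoch(self, epoch: int) -> None:
        self.opt.lr = self.base_lr * self.gamma ** (epoch // self.step_every)
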