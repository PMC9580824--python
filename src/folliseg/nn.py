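"""Minimal reverse-mode neural-network layers on numpy arrays.

A small layer library sufficient for an attention-gated encoder–decoder:
3x3 convolutions (im2col + BLAS matmul), 1x1 convolutions with optional
stride, instance normalisation, ReLU/sigmoid, 2x2 max pooling, 2x2
transposed convolution, nearest-neighbour upsampling, a differentiable
Sobel edge-magnitude op, and an Adam optimiser.

Tensors are ``float32`` arrays in channels-last layout ``(N, H, W, C)`` —
with channels last, the im2col patch matrix is a contiguous concatenation
of nine shifted views and every reshape around the BLAS call is free.
Each layer caches what its backward pass needs during ``forward``; a layer
instance is therefore used at most once per forward/backward cycle.
Everything is deterministic given the initialisation RNG.
"""

from __future__ import annotations

import numpy as np

from .edge_ops import MAX_GRADIENT_MAGNITUDE, SOBEL_KX, SOBEL_KY

__all__ = [
    "Param", "Layer", "Conv2d", "Conv1x1", "InstanceNorm2d", "ReLU", "Sigmoid",
    "MaxPool2", "ConvTranspose2x2", "UpsampleNearest2", "SobelEdgeMagnitude",
    "Adam", "sigmoid",
]

DTYPE = np.float32

_OFFSETS3 = [(di, dj) for di in range(3) for dj in range(3)]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patch matrix for a same-padded 3x3 conv.

    Column block ``k = 3*di + dj`` holds the input shifted by offset
    (di-1, dj-1); within a block, channels keep their order.
    """
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.concatenate(
        [xp[:, di:di + h, dj:dj + w, :] for di, dj in _OFFSETS3], axis=-1)
    return cols.reshape(n * h * w, 9 * c)


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding, same output size; He init."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 9))
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin, 3, 3)))
        self.bias = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _wmat(self) -> np.ndarray:
        # (9*cin, cout) matching the im2col column order (offset-major)
        return self.weight.data.transpose(2, 3, 1, 0).reshape(9 * self.cin, self.cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cols = _im2col3(x)
        y = cols @ self._wmat() + self.bias.data
        self._cols, self._shape = cols, x.shape
        return y.reshape(n, h, w, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g = gy.reshape(n * h * w, self.cout)
        dwmat = self._cols.T @ g
        self.weight.grad += dwmat.reshape(3, 3, self.cin, self.cout).transpose(3, 2, 0, 1)
        self.bias.grad += g.sum(axis=0)
        self._cols = None
        # input gradient = same-padded conv of gy with the 180-deg-rotated
        # kernels, channels transposed (the exact adjoint for stride-1 zero pad)
        wflip = self.weight.data[:, :, ::-1, ::-1].transpose(2, 3, 0, 1)
        gx = _im2col3(gy) @ wflip.reshape(9 * self.cout, self.cin)
        return gx.reshape(n, h, w, c)


class Conv1x1(Layer):
    """1x1 convolution with optional stride (used by attention gates)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1):
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.bias = Param(np.zeros(cout))
        self.stride = stride
        self._x: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        xs = x[:, ::self.stride, ::self.stride, :] if self.stride > 1 else x
        xs = np.ascontiguousarray(xs)
        self._x = xs
        n, h, w, c = xs.shape
        y = xs.reshape(-1, c) @ self.weight.data.T + self.bias.data
        return y.reshape(n, h, w, -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, cout = gy.shape
        g = gy.reshape(-1, cout)
        xs = self._x
        self.weight.grad += g.T @ xs.reshape(-1, xs.shape[-1])
        self.bias.grad += g.sum(axis=0)
        gxs = (g @ self.weight.data).reshape(xs.shape)
        self._x = None
        if self.stride == 1:
            return gxs
        gx = np.zeros(self._shape, dtype=DTYPE)
        gx[:, ::self.stride, ::self.stride, :] = gxs
        return gx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation with affine parameters.

    Batch-size independent and identical in training and inference, which
    keeps small-batch training (batch size 4) stable and reproducible.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += np.sum(gy * xhat, axis=(0, 1, 2))
        self.beta.grad += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma.data
        m1 = gxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(1, 2), keepdims=True)
        self._xhat = self._inv_std = None
        return inv_std * (gxhat - m1 - xhat * m2)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gy, 0.0).astype(DTYPE, copy=False)
        self._mask = None
        return g


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._y * (1.0 - self._y)
        self._y = None
        return g


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (ties resolved to the first position)."""

    def __init__(self) -> None:
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.maximum(np.maximum(x[:, 0::2, 0::2], x[:, 0::2, 1::2]),
                       np.maximum(x[:, 1::2, 0::2], x[:, 1::2, 1::2]))
        self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, y = self._x, self._y
        gx = np.zeros_like(x)
        taken = np.zeros(y.shape, dtype=bool)
        for a in (0, 1):
            for b in (0, 1):
                sl = x[:, a::2, b::2]
                hit = (sl == y) & ~taken
                gx[:, a::2, b::2] = np.where(hit, gy, 0.0)
                taken |= hit
        self._x = self._y = None
        return gx


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2)))
        self.bias = Param(np.zeros(cout))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, c = x.shape
        cout = self.weight.data.shape[1]
        # w4: (cin, 2, 2, cout) so the matmul output reshapes freely
        w4 = self.weight.data.transpose(0, 2, 3, 1).reshape(c, 4 * cout)
        y6 = (x.reshape(-1, c) @ w4).reshape(n, h, w, 2, 2, cout)
        y = y6.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, cout)
        return np.ascontiguousarray(y) + self.bias.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, c = x.shape
        cout = self.weight.data.shape[1]
        g6 = np.ascontiguousarray(
            gy.reshape(n, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(-1, 4 * cout)
        dw4 = x.reshape(-1, c).T @ g6
        self.weight.grad += dw4.reshape(c, 2, 2, cout).transpose(0, 3, 1, 2)
        self.bias.grad += gy.sum(axis=(0, 1, 2))
        w4 = self.weight.data.transpose(0, 2, 3, 1).reshape(c, 4 * cout)
        gx = (g6 @ w4.T).reshape(x.shape)
        self._x = None
        return gx


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = gy.shape
        return gy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def _sobel_pair(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric-padded Sobel correlation on (N, H, W, C); returns (gx, gy)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="symmetric")
    h, w = x.shape[1], x.shape[2]
    gx = np.zeros_like(x)
    gyv = np.zeros_like(x)
    for di in range(3):
        for dj in range(3):
            sl = xp[:, di:di + h, dj:dj + w, :]
            if SOBEL_KX[di, dj] != 0.0:
                gx = gx + DTYPE(SOBEL_KX[di, dj]) * sl
            if SOBEL_KY[di, dj] != 0.0:
                gyv = gyv + DTYPE(SOBEL_KY[di, dj]) * sl
    return gx, gyv


def _unpad_symmetric_adjoint(gp: np.ndarray) -> np.ndarray:
    """Adjoint of 1-pixel symmetric padding on the two spatial axes."""
    g = gp[:, 1:-1, 1:-1, :].copy()
    g[:, 0, :, :] += gp[:, 0, 1:-1, :]
    g[:, -1, :, :] += gp[:, -1, 1:-1, :]
    g[:, :, 0, :] += gp[:, 1:-1, 0, :]
    g[:, :, -1, :] += gp[:, 1:-1, -1, :]
    g[:, 0, 0, :] += gp[:, 0, 0, :]
    g[:, 0, -1, :] += gp[:, 0, -1, :]
    g[:, -1, 0, :] += gp[:, -1, 0, :]
    g[:, -1, -1, :] += gp[:, -1, -1, :]
    return g


class SobelEdgeMagnitude(Layer):
    """Differentiable soft-edge head: normalised Sobel gradient magnitude.

    Forward matches :func:`folliseg.edge_ops.soft_edge` (symmetric padding,
    division by the maximum attainable magnitude).  The gradient is taken
    as 0 at exact zero-magnitude pixels.
    """

    def __init__(self) -> None:
        self._gx: np.ndarray | None = None
        self._gy: np.ndarray | None = None
        self._mag: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        gx, gyv = _sobel_pair(x)
        mag = np.sqrt(gx * gx + gyv * gyv)
        self._gx, self._gy, self._mag = gx, gyv, mag
        return (mag / DTYPE(MAX_GRADIENT_MAGNITUDE)).astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        safe = np.where(self._mag > 0, self._mag, 1.0)
        scale = gy / (safe * DTYPE(MAX_GRADIENT_MAGNITUDE))
        scale = np.where(self._mag > 0, scale, 0.0)
        dgx = scale * self._gx
        dgy = scale * self._gy
        n, h, w, c = gy.shape
        gp = np.zeros((n, h + 2, w + 2, c), dtype=DTYPE)
        for di in range(3):
            for dj in range(3):
                if SOBEL_KX[di, dj] != 0.0:
                    gp[:, di:di + h, dj:dj + w, :] += DTYPE(SOBEL_KX[di, dj]) * dgx
                if SOBEL_KY[di, dj] != 0.0:
                    gp[:, di:di + h, dj:dj + w, :] += DTYPE(SOBEL_KY[di, dj]) * dgy
        self._gx = self._gy = self._mag = None
        return _unpad_symmetric_adjoint(gp)


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
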