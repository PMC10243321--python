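"""Minimal CNN engine in numpy: layers, backprop, and the Adam optimizer.

Only what the portal-dose U-net needs is implemented: zero-padded "same"
2D convolutions (expressed as a handful of BLAS matmuls, one per kernel
tap), ReLU, 2x2 max pooling, 2x nearest-neighbor upsampling, channel
concatenation, and mean-squared-error loss.  Arrays are NHWC float32.

Layers cache what their backward pass needs; ``backward`` accumulates
parameter gradients in ``Param.grad`` and returns the gradient with respect
to the layer input.  Everything is deterministic for a fixed seed on a
single device.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "mse_loss",
    "glorot_uniform",
]

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(
    shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2D:
    """Zero-padded stride-1 "same" convolution, kernel k x k (k odd) or 1 x 1.

    Weights (k, k, c_in, c_out), Glorot-uniform; biases (c_out,), zeros.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        k = kernel_size
        fan_in = k * k * c_in
        fan_out = k * k * c_out
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.weight = Param(glorot_uniform((k, k, c_in, c_out), fan_in, fan_out, rng))
        self.bias = Param(np.zeros(c_out, dtype=DTYPE))
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    @property
    def n_params(self) -> int:
        return self.weight.value.size + self.bias.value.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        pad = self.k // 2
        if pad:
            xp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in), dtype=DTYPE)
            xp[:, pad : pad + h, pad : pad + w, :] = x
        else:
            xp = x
        self._xp = xp
        out = np.empty((n, h, w, self.c_out), dtype=DTYPE)
        out[:] = self.bias.value
        flat_out = out.reshape(-1, self.c_out)
        wv = self.weight.value
        for di in range(self.k):
            for dj in range(self.k):
                sl = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
                flat_out += sl @ wv[di, dj]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w, _ = dy.shape
        pad = self.k // 2
        dy_flat = dy.reshape(-1, self.c_out)
        self.bias.grad += dy_flat.sum(axis=0)
        wv = self.weight.value
        dxp = np.zeros_like(xp)
        for di in range(self.k):
            for dj in range(self.k):
                sl = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
                self.weight.grad[di, dj] += sl.T @ dy_flat
                dxp[:, di : di + h, dj : dj + w, :] += (dy_flat @ wv[di, dj].T).reshape(
                    n, h, w, self.c_in
                )
        self._xp = None
        if pad:
            return dxp[:, pad : pad + h, pad : pad + w, :]
        return dxp


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, DTYPE(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, DTYPE(0))
        self._mask = None
        return out


class MaxPool2:
    """2x2 max pooling, stride 2; gradient routed to the first argmax."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling needs even spatial dimensions")
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h // 2, w // 2, 4, c)
        )
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        onehot = (
            np.arange(4, dtype=np.int64)[None, None, None, :, None] == self._idx[:, :, :, None, :]
        )
        dxr = np.where(onehot, dy[:, :, :, None, :], DTYPE(0))
        dx = (
            dxr.reshape(n, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )
        self._idx = None
        return np.ascontiguousarray(dx, dtype=DTYPE)


class Upsample2:
    """2x nearest-neighbor upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = (pred - target).astype(DTYPE)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = diff * DTYPE(2.0 / diff.size)
    return loss, grad


class Adam:
    """Adam with bias correction; never sees non-trainable tensors."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-6,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = DTYPE(self.beta1), DTYPE(self.beta2)
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            mhat = m / DTYPE(bc1)
            vhat = v / DTYPE(bc2)
            p.value -= DTYPE(self.lr) * mhat / (np.sqrt(vhat) + DTYPE(self.epsilon))
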