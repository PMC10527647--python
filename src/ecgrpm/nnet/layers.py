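"""Differentiable layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during forward; backward
consumes the upstream gradient and returns the gradient with respect to
the layer input, accumulating parameter gradients into ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """Unfold (N, C, H, W) into (N*OH*OW, C*k*k) patch rows."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i: i + stride * oh: stride,
                                  j: j + stride * ow: stride]
    return cols.transpose(0, 4, 5, 1, 2, 3).reshape(n * oh * ow, -1), (n, c, h, w, oh, ow)


def col2im(cols: np.ndarray, shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Fold patch-row gradients back onto the (N, C, H, W) input."""
    n, c, h, w, oh, ow = shape
    cols = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i: i + stride * oh: stride,
               j: j + stride * ow: stride] += cols[:, :, i, j]
    return xp[:, :, pad: pad + h, pad: pad + w] if pad else xp


class Conv2d(Layer):
    """2-D convolution (no bias; batch norm supplies the shift)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.weight = Param(w, name + ".weight")
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, shape = im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.weight.data.T
        n, _, _, _, oh, ow = shape
        self._cache = (cols, shape)
        return out.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        n, _, _, _, oh, ow = shape
        drows = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out)
        self.weight.grad += drows.T @ cols
        dcols = drows @ self.weight.data
        return col2im(dcols, shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(c), name + ".gamma")
        self.beta = Param(np.zeros(c), name + ".beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        # standard batch-norm gradient, vectorized per channel
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int, pad: int = 0) -> None:
        self.k, self.stride, self.pad = k, stride, pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        # pad with -inf so padded cells never win the max
        cols, shape = im2col(
            np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                   constant_values=-np.inf) if self.pad else x,
            self.k, self.stride, 0)
        n2, c2, h2, w2, oh, ow = shape
        patches = cols.reshape(n * oh * ow, c, self.k * self.k)
        arg = patches.argmax(axis=2)
        out = np.take_along_axis(patches, arg[:, :, None], axis=2)[:, :, 0]
        self._cache = (arg, shape, (n, c, h, w))
        return out.reshape(n, oh, ow, c).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, shape, orig = self._cache
        n, c, h, w = orig
        _, _, hp, wp, oh, ow = shape
        drows = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, c)
        dpatches = np.zeros((n * oh * ow, c, self.k * self.k), dtype=dout.dtype)
        np.put_along_axis(dpatches, arg[:, :, None], drows[:, :, None], axis=2)
        dx_p = col2im(dpatches.reshape(n * oh * ow, -1), shape, self.k, self.stride, 0)
        return dx_p[:, :, self.pad: self.pad + h, self.pad: self.pad + w] \
            if self.pad else dx_p


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               dout.shape + (h, w)).astype(dout.dtype).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None,
                 name: str = "fc") -> None:
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.weight = Param(w, name + ".weight")
        self.bias = Param(np.zeros(d_out), name + ".bias")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
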