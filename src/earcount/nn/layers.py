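"""Minimal CPU neural-network layers used by the kernel classifier and the
center regressor.

Everything runs in float32 with NHWC tensor layout.  Convolutions are
unpadded, stride 1, and are evaluated through an explicit im2col buffer so
the inner product runs as one BLAS matmul; the col2im backward pass scatters
gradients with a small loop over the kernel offsets.  The stack is
deliberately tiny — just the layer types the two architectures need — and is
bit-reproducible for a fixed seed on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "AvgPool",
    "MaxPool",
    "Flatten",
    "Dense",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Xavier/Glorot uniform initialisation, variance 2/(fan_in+fan_out)."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base class: forward/backward plus flat parameter and gradient lists."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list:
        return []

    @property
    def grads(self) -> list:
        return []

    def output_shape(self, input_shape: tuple) -> tuple:
        return input_shape


class Conv2D(Layer):
    """Unpadded stride-1 convolution with bias.

    Evaluated as a sum of k*k shifted (M, C) @ (C, O) matmuls — one per
    filter tap — over contiguous slab copies of the input.  For 3x3 filters
    this keeps every copy a large memcpy and every product a BLAS gemm,
    which is far faster in numpy than an explicit im2col buffer.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        k = kernel_size
        fan_in = k * k * in_channels
        fan_out = k * k * out_channels
        self.W = glorot_uniform(rng, (k, k, in_channels, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.k = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=False):
        k, c = self.k, self.in_channels
        n, h, w, _ = x.shape
        oh, ow = h - k + 1, w - k + 1
        m = n * oh * ow
        slabs = np.empty((k * k, m, c), dtype=np.float32)
        view = slabs.reshape(k * k, n, oh, ow, c)
        out = None
        for i in range(k):
            for j in range(k):
                t = i * k + j
                view[t] = x[:, i : i + oh, j : j + ow, :]
                prod = slabs[t] @ self.W[i, j]
                out = prod if out is None else out.__iadd__(prod)
        out += self.b
        if train:
            self._cache = (slabs, x.shape)
        return out.reshape(n, oh, ow, self.out_channels)

    def backward(self, dout):
        slabs, x_shape = self._cache
        k = self.k
        n, oh, ow, _ = dout.shape
        dflat = dout.reshape(n * oh * ow, self.out_channels).astype(np.float32, copy=False)
        self.db[...] = dflat.sum(axis=0)
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                t = i * k + j
                self.dW[i, j] = slabs[t].T @ dflat
                dslab = dflat @ self.W[i, j].T
                dx[:, i : i + oh, j : j + ow, :] += dslab.reshape(n, oh, ow, -1)
        self._cache = None
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def output_shape(self, input_shape):
        h, w, _ = input_shape
        return (h - self.k + 1, w - self.k + 1, self.out_channels)


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial axes for 4-D input).

    Inference uses exponentially accumulated running statistics.
    """

    def __init__(self, num_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(num_features, dtype=np.float32)
        self.beta = np.zeros(num_features, dtype=np.float32)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def _axes(self, x):
        return (0, 1, 2) if x.ndim == 4 else (0,)

    def forward(self, x, train=False):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            m = x.size // x.shape[-1]
            self._cache = (xhat, inv_std.astype(np.float32), m, axes)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dout):
        xhat, inv_std, m, axes = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = inv_std / m * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._cache = None
        return dx.astype(np.float32)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class AvgPool(Layer):
    """Average pooling with square window; supports stride != window size."""

    def __init__(self, size: int, stride: int):
        self.size = size
        self.stride = stride

    def forward(self, x, train=False):
        k, s = self.size, self.stride
        n, h, w, c = x.shape
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        out = np.zeros((n, oh, ow, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += x[:, i : i + oh * s : s, j : j + ow * s : s, :]
        out /= k * k
        if train:
            self._x_shape = x.shape
        return out

    def backward(self, dout):
        k, s = self.size, self.stride
        n, oh, ow, c = dout.shape
        dx = np.zeros(self._x_shape, dtype=np.float32)
        g = dout / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh * s : s, j : j + ow * s : s, :] += g
        return dx

    def output_shape(self, input_shape):
        h, w, c = input_shape
        k, s = self.size, self.stride
        return ((h - k) // s + 1, (w - k) // s + 1, c)


class MaxPool(Layer):
    """Max pooling with non-overlapping windows (stride == window size)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        k = self.size
        n, h, w, c = x.shape
        oh, ow = h // k, w // k
        stacked = x[:, : oh * k, : ow * k, :].reshape(n, oh, k, ow, k, c)
        stacked = stacked.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, k * k, c)
        out = stacked.max(axis=3)
        if train:
            self._argmax = stacked.argmax(axis=3)
            self._x_shape = x.shape
        return out

    def backward(self, dout):
        k = self.size
        n, oh, ow, c = dout.shape
        dstack = np.zeros((n, oh, ow, k * k, c), dtype=np.float32)
        idx = self._argmax
        np.put_along_axis(dstack, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dstack = dstack.reshape(n, oh, ow, k, k, c).transpose(0, 1, 3, 2, 4, 5)
        dx[:, : oh * k, : ow * k, :] = dstack.reshape(n, oh * k, ow * k, c)
        self._argmax = None
        return dx

    def output_shape(self, input_shape):
        h, w, c = input_shape
        return (h // self.size, w // self.size, c)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def output_shape(self, input_shape):
        return (self.W.shape[1],)
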