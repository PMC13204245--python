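"""Minimal CPU neural-network engine (numpy) used by the compact CNN.

Layers follow a plain forward/backward contract on NCHW batches: each
layer caches what its backward pass needs, ``backward`` receives the
gradient w.r.t. its output and returns the gradient w.r.t. its input,
accumulating parameter gradients on ``Param.grad``.  Gradients of every
layer are verified against central finite differences in the test suite.

Design notes
------------
* Convolutions are 3x3 "same" (zero padding), computed by im2col + matmul.
* Max-pool backward routes the gradient to the first (row-major) argmax of
  each 2x2 block; average pool spreads it uniformly; wavelet pooling uses
  the exact linear adjoint (inverse DWT with zero details).
* Batch norm keeps running statistics for evaluation mode.
* Adam with classic (coupled) L2 weight decay on weights only.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .pooling import avg_pool2, max_pool2, wavelet_pool2, wavelet_pool_adjoint
from .wavelets import FilterBank


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in L2 weight decay


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution with 'same' zero padding, He-normal init."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel: int = 3):
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel, kernel))
        self.weight = Param(w, decay=True)
        self.bias = Param(np.zeros(out_channels), decay=False)
        self.kernel = kernel
        self._cols: Optional[np.ndarray] = None
        self._xshape = None

    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((b, c, k * k, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[:, :, i:i + h, j:j + w]
        return cols.reshape(b, c * k * k, h * w)

    def forward(self, x, train=False, rng=None):
        b, c, h, w = x.shape
        cols = self._im2col(x)                       # (B, C*k*k, H*W)
        self._cols, self._xshape = cols, x.shape
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        wmat = wmat.astype(x.dtype, copy=False)
        out = np.matmul(wmat, cols)                  # batched GEMM
        out += self.bias.value.astype(x.dtype)[None, :, None]
        return out.reshape(b, -1, h, w)

    def backward(self, grad):
        b, c, h, w = self._xshape
        k = self.kernel
        p = k // 2
        go = grad.reshape(b, grad.shape[1], h * w)   # (B, O, H*W)
        wmat = self.weight.value.reshape(go.shape[1], -1).astype(grad.dtype, copy=False)
        dw = np.matmul(go, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        self.bias.grad += go.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T, go)
        dcols = dcols.reshape(b, c, k * k, h, w)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i * k + j]
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2D(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        mean = mean.astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        gamma = self.gamma.value.astype(x.dtype)
        beta = self.beta.value.astype(x.dtype)
        return gamma[None, :, None, None] * xhat + beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value.astype(grad.dtype)[None, :, None, None]
        if not train:
            return g * inv_std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return avg_pool2(x)

    def backward(self, grad):
        b, c, h, w = self._in_shape
        up = np.repeat(np.repeat(grad, 2, axis=-2), 2, axis=-1) * 0.25
        return up[..., :h, :w]


class MaxPool2(Layer):
    """2x2 stride-2 max pooling; ties route to the first row-major index."""

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        b, c, h, w = x.shape
        blocks = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(b, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)          # first max wins
        return flat.max(axis=-1)

    def backward(self, grad):
        b, c, h, w = self._in_shape
        flat = np.zeros((b, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        blocks = flat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(b, c, h, w)


class WaveletPool2(Layer):
    """LL-subband pooling with the exact linear adjoint as backward."""

    def __init__(self, fb: FilterBank):
        self.fb = fb

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return wavelet_pool2(x, self.fb)

    def backward(self, grad):
        return wavelet_pool_adjoint(grad, self.fb, self._in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._in_shape).copy()


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Param(w, decay=True)
        self.bias = Param(np.zeros(out_features), decay=False)

    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def forward(self, x, train=False, rng=None):
        self._x = x
        w = self.weight.value.astype(x.dtype, copy=False)
        return x @ w + self.bias.value.astype(x.dtype)

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.astype(grad.dtype, copy=False).T


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float = 0.5):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential:
    """An ordered layer stack with partial forward/backward access."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None,
                start: int = 0, stop: Optional[int] = None) -> np.ndarray:
        for layer in self.layers[start:stop]:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad: np.ndarray, start: Optional[int] = None,
                 stop: int = 0) -> np.ndarray:
        """Backpropagate from layer ``start`` (exclusive end) down to ``stop``."""
        for layer in reversed(self.layers[stop:start]):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"layer{i}.param{j}"] = p.value.copy()
            if isinstance(layer, BatchNorm2D):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value[...] = state[f"layer{i}.param{j}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


class Adam:
    """Adam with classic L2 weight decay added to the raw gradient."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
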