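"""Minimal CNN building blocks in numpy.

Just enough machinery for the small image classifiers in this package:
strided 2-D convolution via im2col, ReLU, 2x2 max pooling, a dense head,
softmax cross-entropy, and SGD with momentum supporting a per-layer
learning-rate multiplier (the transfer-learning convention of training a
new head faster than the carried-over feature layers).

Arrays are NCHW float32. Everything is deterministic given the generator
passed to ``init``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: parameter dicts plus a learning-rate multiplier."""

    lr_mult: float = 1.0

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> dict:
        return {}

    @property
    def grads(self) -> dict:
        return {}


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N * oh * ow, C * k * k) patch matrix."""
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    s = x.strides
    shape = (n, c, oh, ow, k, k)
    strides = (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3])
    patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    col = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(col), oh, ow


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 lr_mult: float = 1.0):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.lr_mult = lr_mult
        self.W = np.zeros((out_ch, in_ch * k * k), dtype=np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.k * self.k
        self.W = (rng.standard_normal(self.W.shape) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(self.out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        col, oh, ow = _im2col(x, self.k, self.stride)
        self._col, self._oh, self._ow = col, oh, ow
        out = col @ self.W.T + self.b
        n = x.shape[0]
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.dW = (g.T @ self._col) / n
        self.db = g.sum(axis=0) / n
        dcol = g @ self.W
        # col2im: scatter patch gradients back onto the input grid
        dx = np.zeros(self._x_shape, dtype=np.float32)
        c, k, s = self._x_shape[1], self.k, self.stride
        dpatch = dcol.reshape(n, oh, ow, c, k, k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += (
                    dpatch[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        return dx

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        h2, w2 = h // 2, w // 2
        v = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        v = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = v.argmax(axis=-1)
        return v.max(axis=-1)

    def backward(self, grad):
        n, c, h2, w2 = grad.shape
        flat = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        v = flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : 2 * h2, : 2 * w2] = v.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, lr_mult: float = 1.0):
        self.n_in, self.n_out = n_in, n_out
        self.lr_mult = lr_mult
        self.W = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng):
        self.W = (rng.standard_normal((self.n_in, self.n_out))
                  * np.sqrt(2.0 / self.n_in)).astype(np.float32)
        self.b = np.zeros(self.n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        n = grad.shape[0]
        self.dW = self._x.T @ grad / n
        self.db = grad.sum(axis=0) / n
        return grad @ self.W.T

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer targets ``y``."""
    return float(-np.mean(np.log(probs[np.arange(y.size), y] + 1e-12)))


class Network:
    """A plain layer stack with softmax cross-entropy training."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: "SGDMomentum") -> float:
        probs = softmax(self.forward(x))
        loss = cross_entropy(probs, y)
        grad = probs.copy()
        grad[np.arange(y.size), y] -= 1.0
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        opt.step(self.layers)
        return loss

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"layer{i}.{name}"] = value.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}.{name}"]


class SGDMomentum:
    """SGD with momentum; effective step is ``lr * layer.lr_mult``."""

    def __init__(self, lr: float, momentum: float = 0.9):
        self.lr, self.momentum = lr, momentum
        self._velocity: dict = {}

    def step(self, layers: list[Layer]) -> None:
        for i, layer in enumerate(layers):
            for name, param in layer.params.items():
                key = (i, name)
                v = self._velocity.get(key)
                if v is None:
                    v = np.zeros_like(param)
                v = self.momentum * v - self.lr * layer.lr_mult * layer.grads[name]
                self._velocity[key] = v
                param += v
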