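"""Minimal convolutional-network primitives in numpy.

The classifiers in :mod:`mycotax.models` need a small, dependency-free,
fully deterministic CNN: forward and backward passes are written out
explicitly (im2col convolutions, 2x2 max pooling, global average pooling,
linear heads) and optimized with stochastic gradient descent with momentum
and L2 weight decay under a softmax cross-entropy loss.  Parameters are
Xavier (Glorot uniform) initialized.

Shapes follow the NCHW convention internally; images enter as uint8 NHWC
and are converted by :func:`to_batch`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def to_batch(images: np.ndarray) -> np.ndarray:
    """uint8 NHWC images -> float32 NCHW in [0, 1]."""
    x = images.astype(np.float32) / 255.0
    return np.ascontiguousarray(np.transpose(x, (0, 3, 1, 2)))


class Layer:
    """A differentiable module with (possibly empty) trainable parameters."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def named_params(self):
        g = self.grads()
        return [(name, p, g[name]) for name, p in self.params().items()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.named_params():
            p[:] = state[name]


class Conv2d(Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = xavier_uniform(rng, (c_out, c_in * k * k), fan_in, fan_out)
        self.b = np.zeros(c_out, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N, H, W, C*k*k)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(np.transpose(cols, (0, 2, 3, 1, 4, 5)))
        self._cols = cols.reshape(N, H, W, C * self.k * self.k)
        self._in_shape = x.shape
        out = self._cols @ self.W.T + self.b
        return np.ascontiguousarray(np.transpose(out, (0, 3, 1, 2)))

    def backward(self, dout):
        N, C, H, W = self._in_shape
        d = np.transpose(dout, (0, 2, 3, 1))  # (N, H, W, c_out)
        self.db[:] = d.sum(axis=(0, 1, 2))
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.dW[:] = d.reshape(-1, self.c_out).T @ flat_cols
        dcols = (d @ self.W).reshape(N, H, W, C, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + H, j : j + W] += np.transpose(dcols[:, :, :, :, i, j], (0, 3, 1, 2))
        return dxp[:, :, p : p + H, p : p + W]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (even input sides required)."""

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # split gradient among ties to keep backward exact
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout):
        N, C, H, W = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(N, C, H, W).astype(np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (H * W), self._shape).astype(np.float32)


class ChannelNorm(Layer):
    """Per-sample, per-channel standardization (no trainable parameters).

    A batch-statistics-free stand-in for batch normalization: it keeps
    activations well-scaled at the reference fine-tuning learning rate while staying
    exactly deterministic and batch-size independent.
    """

    eps = 1e-5

    def forward(self, x, train=False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat

    def backward(self, dout):
        n = dout.shape[2] * dout.shape[3]
        dmean = dout.mean(axis=(2, 3), keepdims=True)
        dvar = (dout * self._xhat).mean(axis=(2, 3), keepdims=True)
        return (dout - dmean - self._xhat * dvar) * self._inv


class FeatureScale(Layer):
    """Multiply features by a fixed gain (no trainable parameters).

    Placed after global pooling, a gain ``g`` rescales the backbone output
    so that head and backbone gradients are usable at a fine-tuning-sized
    learning rate; it is part of the architecture, not of the optimizer.
    """

    def __init__(self, gain: float):
        self.gain = float(gain)

    def forward(self, x, train=False):
        return x * self.gain

    def backward(self, dout):
        return dout * self.gain


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = xavier_uniform(rng, (d_out, d_in), d_in, d_out)
        self.b = np.zeros(d_out, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[:] = dout.T @ self._x
        self.db[:] = dout.sum(axis=0)
        return dout @ self.W


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out.append((f"layer{i}.{name}", p, layer.grads()[name]))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.named_params():
            p[:] = state[name]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """Mean softmax cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class SGD:
    """SGD with momentum and decoupled-from-nothing classic L2 weight decay:
    ``v <- m*v + g + wd*w;  w <- w - lr*v``."""

    def __init__(self, modules, lr: float, momentum: float, weight_decay: float):
        self.modules = list(modules)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity: dict[int, dict[str, np.ndarray]] = {}

    def step(self):
        for mod in self.modules:
            for name, p, g in mod.named_params():
                vstore = self.velocity.setdefault(id(mod), {})
                v = vstore.setdefault(name, np.zeros_like(p))
                v *= self.momentum
                v += g + self.weight_decay * p
                p -= self.lr * v
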