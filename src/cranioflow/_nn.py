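"""Minimal CPU neural-network engine (forward + backprop) used by models.

Layers operate on NCHW float32 batches.  Convolutions use im2col so the
heavy lifting is BLAS matrix multiplication; max pooling and the col2im
scatter are vectorised over the kernel footprint.  Weight initialisation
is Glorot (Xavier) uniform with zero biases; all stochastic layers draw
from generators seeded at construction, so training runs are exactly
reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "BatchNorm1d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "Dropout",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "bce_loss",
    "l1_penalty",
    "conv_out_size",
    "pool_out_size",
]

_EPS = 1e-7


def conv_out_size(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def pool_out_size(size: int, kernel: int, stride: int) -> int:
    return (size - kernel) // stride + 1


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: parameter dicts plus forward/backward passes."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: parameter keys subject to L1 weight regularisation
        self.weight_keys: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def num_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N*OH*OW, C*k*k) patch matrix."""
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, OH, OW, k, k) -> (N, OH, OW, C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    n, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n * oh * ow, -1), (n, oh, ow)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Scatter-add patch gradients back to the padded input."""
    n, c, hp, wp = shape
    dxp = np.zeros(shape, dtype=np.float32)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, i, j
            ]
    return dxp


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, kernel, stride, pad
        fan_in = cin * kernel * kernel
        fan_out = cout * kernel * kernel
        self.params = {
            "W": glorot_uniform(rng, (fan_in, cout), fan_in, fan_out),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self.weight_keys = ("W",)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        self._xp_shape = x.shape
        cols, (n, oh, ow) = _im2col(x, self.k, self.stride)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.grads["W"] = self._cols.T @ dmat
        self.grads["b"] = dmat.sum(axis=0)
        dcols = dmat @ self.params["W"].T
        dxp = _col2im(dcols, self._xp_shape, self.k, self.stride, self._oh, self._ow)
        if self.pad:
            dxp = dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class _BatchNorm(Layer):
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(dim, dtype=np.float32),
            "beta": np.zeros(dim, dtype=np.float32),
        }
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)

    def _axes(self, x):
        raise NotImplementedError

    def _shape(self, x):
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes(x)
        shape = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        self._axes_cache, self._shape_cache = axes, shape
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes, shape = self._axes_cache, self._shape_cache
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shape)
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)
        ) / self._std.reshape(shape)
        return dx


class BatchNorm2d(_BatchNorm):
    def _axes(self, x):
        return (0, 2, 3)

    def _shape(self, x):
        return (1, -1, 1, 1)


class BatchNorm1d(_BatchNorm):
    def _axes(self, x):
        return (0,)

    def _shape(self, x):
        return (1, -1)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.k, self.stride = kernel, stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, self.k * self.k)
        self._arg = flat.argmax(axis=-1)
        self._oh, self._ow = oh, ow
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        dx = np.zeros(self._shape, dtype=np.float32)
        oh, ow = self._oh, self._ow
        for i in range(k):
            for j in range(k):
                mask = self._arg == (i * k + j)
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += dout * mask
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Spatial averaging that keeps the depth dimension: (N,C,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("global average pooling needs a spatial feature map")
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": glorot_uniform(rng, (din, dout), din, dout),
            "b": np.zeros(dout, dtype=np.float32),
        }
        self.weight_keys = ("W",)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainable_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.trainable and l.params]

    def num_params(self) -> int:
        return sum(l.num_params() for l in self.layers if l.trainable)

    def state(self) -> list[dict[str, np.ndarray]]:
        out = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, _BatchNorm):
                d["running_mean"] = layer.running_mean.copy()
                d["running_var"] = layer.running_var.copy()
            out.append(d)
        return out

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, d in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = np.asarray(d[k], dtype=np.float32)
            if isinstance(layer, _BatchNorm):
                layer.running_mean = np.asarray(d["running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(d["running_var"], dtype=np.float32)


class Adam:
    """Adam optimiser (first-moment decay 0.9, second-moment 0.999, eps 1e-8)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.trainable and l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** self.t)
                vhat = v[k] / (1 - b2 ** self.t)
                layer.params[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all batch/label entries, with gradient."""
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    y = targets.astype(np.float32)
    loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    grad = (p - y) / (p * (1 - p)) / p.size
    return loss, grad.astype(np.float32)


def l1_penalty(model: Sequential, lam: float) -> float:
    """lam times the L1 norm of all convolution/dense kernels."""
    if lam == 0:
        return 0.0
    total = 0.0
    for layer in model.trainable_layers():
        for k in layer.weight_keys:
            total += float(np.abs(layer.params[k]).sum())
    return lam * total


def apply_l1_grads(model: Sequential, lam: float) -> None:
    if lam == 0:
        return
    for layer in model.trainable_layers():
        for k in layer.weight_keys:
            layer.grads[k] = layer.grads[k] + lam * np.sign(layer.params[k])
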