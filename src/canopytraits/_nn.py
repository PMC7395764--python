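"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the trait-regression network needs: 2-D convolution (stride 1,
optional zero padding) via im2col + BLAS matmul, 2x2 average/max pooling,
ReLU, inverted dropout, a dense layer, mean-squared-error loss and SGD with
momentum.  All tensors are float32 NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_normal(rng: np.random.Generator, shape: tuple[int, ...],
              fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 convolution with square kernel and symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.pad = in_ch, out_ch, kernel, pad
        fan_in = in_ch * kernel * kernel
        self.params["W"] = he_normal(rng, (fan_in, out_ch), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = x.shape[2] - k + 1, x.shape[3] - k + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (n,c,ho,wo,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(n * ho * wo, c * k * k)
        out = cols @ self.params["W"] + self.params["b"]
        self._cols = cols if train else None
        self._xshape = (n, c, h, w, ho, wo)
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dout, need_dx: bool = True):
        n, c, h, w, ho, wo = self._xshape
        k, p = self.k, self.pad
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)) \
            .reshape(n * ho * wo, self.out_ch)
        cols = self._cols
        self.grads["W"] = cols.T @ dmat
        self.grads["b"] = dmat.sum(axis=0)
        self._cols = None
        if not need_dx:
            return None
        dcols = dmat @ self.params["W"].T  # (n*ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        hp, wp = h + 2 * p, w + 2 * p
        # accumulate in NHWC to keep the scatter contiguous, transpose once
        dxp = np.zeros((n, hp, wp, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + ho, j:j + wo, :] += dcols[:, :, :, :, i, j]
        dxp = dxp.transpose(0, 3, 1, 2)
        return np.ascontiguousarray(
            dxp[:, :, p:hp - p, p:wp - p]) if p else np.ascontiguousarray(dxp)


class AvgPool2(Layer):
    """2x2 average pooling with stride 2; input sides must be even."""

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        dx = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        return dx.astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train, rng=None):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: identity at inference time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = he_normal(rng, (in_dim, out_dim), in_dim)
        self.params["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x, train, rng=None):
        self._x = x if train else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over batch and outputs, with its gradient."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff ** 2))
    dpred = (2.0 / diff.size) * diff
    return loss, dpred


class SGDMomentum:
    """SGD with classical momentum and optional global-norm gradient clipping
    (keeps early training stable when the loss surface is steep)."""

    def __init__(self, layers: list[Layer], momentum: float = 0.9,
                 clip_norm: float | None = 5.0) -> None:
        self.layers = [l for l in layers if l.params]
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [{k: np.zeros_like(v) for k, v in l.params.items()}
                         for l in self.layers]

    def step(self, lr: float) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = 0.0
            for layer in self.layers:
                for g in layer.grads.values():
                    sq += float(np.sum(g.astype(np.float64) ** 2))
            gnorm = np.sqrt(sq)
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
        for layer, vel in zip(self.layers, self.velocity):
            for key, param in layer.params.items():
                g = layer.grads[key].astype(np.float32) * scale
                vel[key] = self.momentum * vel[key] - lr * g
                param += vel[key]


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            if i == 0 and isinstance(layer, Conv2D):
                layer.backward(dout, need_dx=False)  # nothing consumes dx
                return
            dout = layer.backward(dout)

    def get_params(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_params(self, params: list[dict[str, np.ndarray]]) -> None:
        for layer, p in zip(self.layers, params):
            for k in layer.params:
                layer.params[k] = p[k].copy()
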