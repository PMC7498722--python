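"""A small, dependency-free convolutional network engine.

Implements exactly the layer vocabulary the feature extractor needs —
same-padded 3x3 convolutions, ReLU, 2x2 stride-2 max pooling (floor
semantics), flatten, global average pooling, dense layers — with
reverse-mode gradients, softmax cross-entropy and an RMSProp optimizer.
Everything is float32 numpy; convolutions are evaluated as shifted tensor
contractions so the heavy lifting stays in BLAS.  Layers carry a
``trainable`` flag so early blocks can be frozen bit-exactly during
fine-tuning.
"""

from __future__ import annotations

import copy

import numpy as np


class Layer:
    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded stride-1 convolution with a k x k kernel (default 3).

    Evaluated as k*k shifted (out_ch, in_ch) tensor contractions against
    cropped views of the zero-padded input, which keeps all heavy work in
    contiguous BLAS calls.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.k = k
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = {
            "W": (scale * rng.standard_normal((out_ch, in_ch, k, k))).astype(np.float32),
            "b": np.zeros(out_ch, dtype=np.float32),
        }

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        xp = self._pad(x)
        W = self.params["W"]
        out = np.zeros((n, self.out_ch, h, w), dtype=x.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                xs = xp[:, :, di : di + h, dj : dj + w]
                # (N, O, H, W) += W[:, :, di, dj] applied over channels
                out += np.tensordot(xs, W[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
        out += self.params["b"][None, :, None, None]
        if train:
            self._xp, self._in_shape = xp, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(self._xp)
        for di in range(self.k):
            for dj in range(self.k):
                xs = self._xp[:, :, di : di + h, dj : dj + w]
                dW[:, :, di, dj] = np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    dout, W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        del self._xp
        p = self.k // 2
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; odd trailing rows/columns are dropped (floor)."""

    @staticmethod
    def _quadrants(x: np.ndarray, h2: int, w2: int):
        return (
            x[:, :, 0 : 2 * h2 : 2, 0 : 2 * w2 : 2],
            x[:, :, 0 : 2 * h2 : 2, 1 : 2 * w2 : 2],
            x[:, :, 1 : 2 * h2 : 2, 0 : 2 * w2 : 2],
            x[:, :, 1 : 2 * h2 : 2, 1 : 2 * w2 : 2],
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        quads = self._quadrants(x, h2, w2)
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        if train:
            self._x, self._out, self._in_shape = x, out, (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        assigned = np.zeros(dout.shape, dtype=bool)
        # route gradient to the first position matching the max (tie-break:
        # top-left first), mirroring a deterministic argmax
        for xq, dq in zip(self._quadrants(self._x, h2, w2), self._quadrants(dx, h2, w2)):
            sel = (xq == self._out) & ~assigned
            dq += np.where(sel, dout, 0)
            assigned |= sel
        del self._x, self._out
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None], self._in_shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_dim)
        self.params = {
            "W": (scale * rng.standard_normal((in_dim, out_dim))).astype(np.float32),
            "b": np.zeros(out_dim, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainable_params(self):
        for layer in self.layers:
            if layer.trainable:
                for name in layer.params:
                    yield layer, name

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        if len(state) != len(self.layers):
            raise ValueError("state does not match model topology")
        for layer, params in zip(self.layers, state):
            layer.params = copy.deepcopy(params)


class RMSProp:
    """Root-mean-square propagation with Keras-style defaults."""

    def __init__(self, lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[tuple[int, str], np.ndarray] = {}

    def step(self, model: Sequential) -> None:
        for layer, name in model.trainable_params():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            cache = self._cache.get(key)
            if cache is None:
                cache = np.zeros_like(layer.params[name])
            cache = self.rho * cache + (1.0 - self.rho) * g * g
            self._cache[key] = cache
            layer.params[name] -= (self.lr * g / (np.sqrt(cache) + self.eps)).astype(np.float32)
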