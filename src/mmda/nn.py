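"""Minimal NumPy neural-network layer library.

Provides exactly what the small encoders and linear classifiers in this
package need: dense/conv/pooling layers with manual backprop, an SGD
optimizer with momentum and weight decay, and seeded initialization.
Layers follow a forward/backward protocol; ``backward`` consumes the
gradient w.r.t. the layer output and returns the gradient w.r.t. the
input while accumulating parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless unless it owns Params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # He-style init; biases start at zero.
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)), "W")
        self.b = Param(np.zeros(d_out), "b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.W.value.shape[0]:
            raise ShapeError(
                f"Linear expected (N, {self.W.value.shape[0]}), got {x.shape}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0  # ReLU'(0) = 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class BatchNorm1d(Layer):
    """Feature standardization using current-batch statistics.

    Always normalizes with the statistics of the batch it sees (no
    running averages), which keeps full-dataset feature extraction
    deterministic and centers/scales features so that cosine geometry
    and entropy objectives behave well downstream.
    """

    def __init__(self, dim: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.affine = affine
        self.gamma = Param(np.ones(dim), "bn_gamma") if affine else None
        self.beta = Param(np.zeros(dim), "bn_beta") if affine else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape[0])
        if self.affine:
            return xhat * self.gamma.value + self.beta.value
        return xhat

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, n = self._cache
        if self.affine:
            self.gamma.grad += (grad_out * xhat).sum(axis=0)
            self.beta.grad += grad_out.sum(axis=0)
            grad_out = grad_out * self.gamma.value
        # standard batch-stat backprop: d/dx of (x - mean)/std
        gsum = grad_out.sum(axis=0)
        gxhat = (grad_out * xhat).sum(axis=0)
        return inv_std * (grad_out - gsum / n - xhat * gxhat / n)


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """x: (N, C, H, W) -> columns (N, H_out*W_out, C*kh*kw), stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    h_out, w_out = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    s0, s1, s2, s3 = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, h_out, w_out, kh, kw),
        strides=(s0, s1, s2, s3, s2, s3),
        writeable=False,
    )
    # (N, H_out, W_out, C, kh, kw) -> (N, H_out*W_out, C*kh*kw)
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, h_out * w_out, c * kh * kw)


class Conv2d(Layer):
    """3x3-style same convolution, stride 1, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator, pad: int | None = None):
        self.ksize = ksize
        self.pad = (ksize // 2) if pad is None else pad
        fan_in = c_in * ksize * ksize
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)), "convW")
        self.b = Param(np.zeros(c_out), "convb")
        self.c_in, self.c_out = c_in, c_out
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ShapeError(f"Conv2d expected {self.c_in} channels, got {c}")
        self._xshape = x.shape
        cols = _im2col(x, self.ksize, self.ksize, self.pad)
        self._cols = cols
        h_out = h + 2 * self.pad - self.ksize + 1
        w_out = w + 2 * self.pad - self.ksize + 1
        out = cols @ self.W.value + self.b.value  # (N, P, c_out)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h_out, w_out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, _, h_out, w_out = grad_out.shape
        g = grad_out.reshape(n, self.c_out, h_out * w_out).transpose(0, 2, 1)  # (N,P,c_out)
        cols = self._cols
        self.W.grad += np.einsum("npk,npo->ko", cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        gcols = g @ self.W.value.T  # (N, P, c_in*k*k)
        # col2im accumulation
        _, c, h, w = self._xshape
        k, pad = self.ksize, self.pad
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        gcols = gcols.reshape(n, h_out, w_out, c, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + h_out, dj : dj + w_out] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx[:, :, pad : pad + h, pad : pad + w]


class AvgPool2d(Layer):
    """Non-overlapping average pooling; input dims must divide the window."""

    def __init__(self, window: int):
        self.window = window
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.window
        if h % k or w % k:
            raise ShapeError(f"AvgPool2d window {k} does not divide ({h},{w})")
        self._xshape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k = self.window
        g = grad_out / (k * k)
        return np.broadcast_to(
            g[:, :, :, None, :, None], (n, c, h // k, k, w // k, k)
        ).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        return np.broadcast_to(grad_out[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class SGD:
    """Minibatch SGD with momentum and (decoupled-from-loss) weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v


def get_state(layer: Layer) -> list[np.ndarray]:
    """Copies of all parameter values (for serialization / frozen snapshots)."""
    return [p.value.copy() for p in layer.params()]


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    params = layer.params()
    if len(params) != len(state):
        raise ShapeError(f"state has {len(state)} arrays, layer has {len(params)} params")
    for p, v in zip(params, state):
        if p.value.shape != v.shape:
            raise ShapeError(f"param shape {p.value.shape} != state shape {v.shape}")
        p.value = np.asarray(v, dtype=np.float64).copy()
        p.grad = np.zeros_like(p.value)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
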