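"""Minimal NumPy neural-network engine with manual gradients.

Small, explicit layer implementations (strided convolution, transposed
convolution, fully connected layers, ReLU/sigmoid, global average pooling)
with hand-written backward passes, plus an Adam optimizer.  Everything runs
in float64 so analytic gradients can be validated against central finite
differences to tight tolerances.

Layers cache what their backward pass needs during ``forward``; ``backward``
consumes the upstream gradient, accumulates parameter gradients in place and
returns the gradient with respect to the layer input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "GlobalAvgPool2d",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation) with zero padding.

    With kernel 5, stride 2, padding 2 the spatial size halves exactly for
    even inputs, which is the downsampling geometry used by the encoder.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 5,
                 stride: int = 2, padding: int = 2, *, rng: np.random.Generator):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel, stride, padding
        fan_in = in_channels * kernel * kernel
        self.W = Param(_he_init(rng, (out_channels, in_channels, kernel, kernel), fan_in))
        self.b = Param(np.zeros(out_channels))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win[:, :, :oh, :ow]  # (n, cin, oh, ow, k, k)
        y = np.tensordot(win, self.W.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        y += self.b.value[None, :, None, None]
        self._cache = (win, (h, w), (oh, ow))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win, (h, w), (oh, ow) = self._cache
        k, s, p = self.k, self.s, self.p
        self.W.grad += np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        n = dy.shape[0]
        dxp = np.zeros((n, self.cin, h + 2 * p, w + 2 * p))
        Wv = self.W.value
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + s * oh:s, dj:dj + s * ow:s] += np.einsum(
                    "fc,nfhw->nchw", Wv[:, :, di, dj], dy)
        return dxp[:, :, p:p + h, p:p + w]


class ConvTranspose2d(Layer):
    """Strided transposed convolution — the adjoint of :class:`Conv2d`.

    Output size is ``(h - 1) * stride - 2 * padding + kernel + output_padding``;
    kernel 5, stride 2, padding 2, output_padding 1 exactly doubles the input.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 5,
                 stride: int = 2, padding: int = 2, output_padding: int = 1,
                 *, rng: np.random.Generator):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p, self.op = kernel, stride, padding, output_padding
        fan_in = in_channels * kernel * kernel
        self.W = Param(_he_init(rng, (in_channels, out_channels, kernel, kernel), fan_in))
        self.b = Param(np.zeros(out_channels))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_size(self, h: int) -> int:
        return (h - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.s, self.p
        hout, wout = self.out_size(h), self.out_size(w)
        hf, wf = (h - 1) * s + k + self.op, (w - 1) * s + k + self.op
        yf = np.zeros((n, self.cout, hf, wf))
        Wv = self.W.value
        for di in range(k):
            for dj in range(k):
                yf[:, :, di:di + s * h:s, dj:dj + s * w:s] += np.einsum(
                    "fc,nfhw->nchw", Wv[:, :, di, dj], x)
        y = yf[:, :, p:p + hout, p:p + wout].copy()
        y += self.b.value[None, :, None, None]
        self._cache = (x, (h, w), (hout, wout), (hf, wf))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (h, w), (hout, wout), (hf, wf) = self._cache
        k, s, p = self.k, self.s, self.p
        n = dy.shape[0]
        dyf = np.zeros((n, self.cout, hf, wf))
        dyf[:, :, p:p + hout, p:p + wout] = dy
        win = sliding_window_view(dyf, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win[:, :, :h, :w]  # (n, cout, h, w, k, k)
        self.W.grad += np.tensordot(x, win, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(win, self.W.value, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.W = Param(_he_init(rng, (in_features, out_features), in_features))
        self.b = Param(np.zeros(out_features))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class GlobalAvgPool2d(Layer):
    """(n, c, h, w) -> (n, c) mean over the spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
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

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with bias correction; ``step`` applies and clears gradients."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.zero_grad()

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
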