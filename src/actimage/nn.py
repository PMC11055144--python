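"""Minimal deterministic CNN engine in NumPy.

Implements exactly the layer set the classification model needs —
valid-padding stride-1 convolution, ReLU, 2x2/2 max pooling, dense
layers, softmax cross-entropy and Adam — with explicit seeded
initialization so training is bit-reproducible on CPU.  Data layout is
NHWC; convolutions are evaluated as im2col tensor contractions, which
lets BLAS do the heavy lifting.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

DTYPE = np.float32


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution, stride 1, bias.  Weights (kh, kw, c_in, c_out)."""

    def __init__(self, kh, kw, c_in, c_out, rng):
        super().__init__()
        std = np.sqrt(2.0 / (kh * kw * c_in))
        self.W = rng.normal(0.0, std, (kh, kw, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        kh, kw = self.W.shape[:2]
        if x.shape[1] < kh or x.shape[2] < kw:
            raise ValidationError(
                f"input {x.shape[1]}x{x.shape[2]} smaller than {kh}x{kw} kernel"
            )
        patches = sliding_window_view(x, (kh, kw), axis=(1, 2))
        # patches: (N, Ho, Wo, C, kh, kw)
        out = np.tensordot(patches, self.W, axes=([3, 4, 5], [2, 0, 1])) + self.b
        if train:
            self._patches = patches
            self._xshape = x.shape
        return out.astype(DTYPE, copy=False)

    def backward(self, dout):
        kh, kw = self.W.shape[:2]
        # (N,Ho,Wo,C,kh,kw) x (N,Ho,Wo,O) -> (C,kh,kw,O)
        dW = np.tensordot(self._patches, dout, axes=([0, 1, 2], [0, 1, 2]))
        self.grads[0][...] = dW.transpose(1, 2, 0, 3)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        # full correlation of dout with the flipped kernel gives dx
        pad = ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0))
        dpad = np.pad(dout, pad)
        dpatches = sliding_window_view(dpad, (kh, kw), axis=(1, 2))
        Wr = self.W[::-1, ::-1]                   # (kh, kw, C, O)
        dx = np.tensordot(dpatches, Wr, axes=([3, 4, 5], [3, 0, 1]))
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/cols are dropped."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : ho * 2, : wo * 2]
        windows = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = windows.reshape(n, ho, wo, c, 4)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, ho, wo, c = dout.shape
        dflat = np.zeros((n, ho, wo, c, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx_c = dflat.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx_c = dx_c.reshape(n, ho * 2, wo * 2, c)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, : ho * 2, : wo * 2] = dx_c
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        if train:
            self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy loss, its gradient wrt logits, and the probs."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(DTYPE), probs


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
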