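"""Minimal CPU convolutional-network engine for 32x32 grayscale regression.

Implements exactly the pieces the T:R regressor needs — 3x3 same-padding
convolution, ReLU, 2x2 max pooling, dense layers, a softplus output head
and an Adam optimiser — with explicit forward/backward passes on numpy
arrays.  The network is small (two feature blocks, a few dense layers)
and trains in minutes on one CPU; all randomness flows through a single
`numpy` Generator so initial weights and batch order are reproducible
bit for bit from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConvNet", "Adam"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


class _Conv3x3:
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._col = self._im2col(x)
        b, h, w = self._col.shape[:3]
        self._in_shape = x.shape
        wm = self.w.reshape(self.w.shape[0], -1)
        out = self._col.reshape(b, h * w, -1) @ wm.T + self.b
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(b, h * w, f)
        colflat = self._col.reshape(b, h * w, -1)
        self.dw[...] = np.einsum("bnf,bnk->fk", dflat, colflat).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=(0, 1))
        dcol = (dflat @ self.w.reshape(f, -1)).reshape(b, h, w, -1, 3, 3)
        c = self._in_shape[1]
        dxp = np.zeros((b, c, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + w] += dcol[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    """2x2 max pooling, stride 2; ties resolved to the first maximum."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        r = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(b, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        dr = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(b, c, h, w)


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


class ConvNet:
    """Conv-pool feature blocks followed by a dense regression head.

    Input: ``(batch, res, res)`` grayscale images; output: one
    non-negative scalar per image (softplus head).
    """

    def __init__(
        self,
        resolution: int = 32,
        filters: tuple[int, ...] = (8, 16),
        dense: tuple[int, ...] = (64, 16),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.resolution = resolution
        self.filters = tuple(filters)
        self.dense_sizes = tuple(dense)
        self.layers: list = []
        c, side = 1, resolution
        for f in filters:
            self.layers += [_Conv3x3(c, f, rng), _ReLU(), _MaxPool2()]
            c, side = f, side // 2
        self.layers.append(_Flatten())
        n_in = c * side * side
        for n_out in dense:
            self.layers += [_Dense(n_in, n_out, rng), _ReLU()]
            n_in = n_out
        self.layers.append(_Dense(n_in, 1, rng))

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_params(self) -> int:
        return sum(w.size for w, _ in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (w, _), new in zip(self.params, weights):
            w[...] = new

    # -- forward / backward ------------------------------------------------
    def forward(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)[:, None, :, :]
        for layer in self.layers:
            x = layer.forward(x)
        self._z = x[:, 0]
        return _softplus(self._z)

    def backward(self, dpred: np.ndarray) -> None:
        dz = (dpred * _sigmoid(self._z))[:, None]
        for layer in reversed(self.layers):
            dz = layer.backward(dz)

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.shape[0] == 0:
            return np.empty(0)
        return np.concatenate(
            [self.forward(images[i:i + batch_size])
             for i in range(0, images.shape[0], batch_size)]
        )


class Adam:
    """Adam optimiser over a model's (param, grad) pairs."""

    def __init__(self, model: ConvNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(w) for w, _ in model.params]
        self.v = [np.zeros_like(w) for w, _ in model.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (w, g), m, v in zip(self.model.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
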