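"""Minimal feed-forward/convolutional network engine on numpy.

Implements exactly the layer vocabulary the °Brix regressors need —
dense, 2-D convolution (channels-last, 'same' padding), batch
normalization, dropout, max/average pooling, ReLU — with reverse-mode
gradients for both the parameters (training) and the network input
(integrated-gradients attribution).  Adam is the only optimizer.

Conventions
-----------
* Dense layers take ``(N, F)`` arrays; convolutional layers take
  ``(N, H, W, C)`` arrays (channels last).
* ``forward(x, training, rng)`` caches whatever ``backward`` needs;
  ``backward(dy)`` returns ``dx`` and stores parameter gradients in
  ``layer.grads`` (same order as ``layer.params``).
* All arithmetic is float64; gradients are verified against central
  finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless unless it declares ``params``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        # He initialization: every Dense here feeds a ReLU
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Normalizes over every axis except the last (the channel axis)."""

    def __init__(self, n_channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._training = training
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma * self._inv_std
        n = dy.size // dy.shape[-1]
        dxhat = dy * self.gamma
        return (self._inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution, channels last.

    Padding follows the usual asymmetric rule: ``(k-1)//2`` before,
    the remainder after, so output spatial dims equal input dims for
    any kernel size.  An optional L2 penalty applies to the kernel.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator, l2_lambda: float = 0.0):
        super().__init__()
        kh, kw = kernel
        scale = np.sqrt(2.0 / (kh * kw * c_in))
        self.W = rng.normal(0.0, scale, size=(kh, kw, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.kernel = (kh, kw)
        self.l2_lambda = l2_lambda

    def _pad(self):
        kh, kw = self.kernel
        return ((kh - 1) // 2, kh - 1 - (kh - 1) // 2,
                (kw - 1) // 2, kw - 1 - (kw - 1) // 2)

    def forward(self, x, training=False, rng=None):
        pt, pb, pl, pr = self._pad()
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        kh, kw = self.kernel
        # (N, H, W, C, kh, kw)
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        self._win = win
        self._xshape = x.shape
        n, h, w, c = x.shape
        # contract (C, kh, kw) against kernel (kh, kw, C, F)
        y = np.tensordot(win, self.W, axes=([3, 4, 5], [2, 0, 1]))
        return y + self.b

    def backward(self, dy):
        kh, kw = self.kernel
        n, h, w, c = self._xshape
        self.grads[0][...] = np.tensordot(
            self._win, dy, axes=([0, 1, 2], [0, 1, 2])
        ).transpose(1, 2, 0, 3)  # (C,kh,kw,F) -> (kh,kw,C,F)
        if self.l2_lambda:
            self.grads[0] += 2.0 * self.l2_lambda * self.W
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        pt, pb, pl, pr = self._pad()
        dxp = np.zeros((n, h + pt + pb, w + pl + pr, c))
        for i in range(kh):
            for j in range(kw):
                # dy (N,H,W,F) @ W[i,j].T (F,C)
                dxp[:, i:i + h, j:j + w, :] += dy @ self.W[i, j].T
        return dxp[:, pt:pt + h, pl:pl + w, :]

    def l2_loss(self) -> float:
        return float(self.l2_lambda * np.sum(self.W ** 2))


class _Pool(Layer):
    def __init__(self, size: tuple[int, int]):
        super().__init__()
        self.size = size

    def _check(self, x):
        ph, pw = self.size
        n, h, w, c = x.shape
        ho, wo = h // ph, w // pw
        if ho < 1 or wo < 1:
            raise ValueError(
                f"pool size {self.size} collapses spatial axes of input "
                f"{h}x{w} below 1"
            )
        return n, h, w, c, ho, wo


class MaxPool2D(_Pool):
    def forward(self, x, training=False, rng=None):
        ph, pw = self.size
        n, h, w, c, ho, wo = self._check(x)
        xr = (x[:, :ho * ph, :wo * pw, :]
              .reshape(n, ho, ph, wo, pw, c)
              .transpose(0, 1, 3, 5, 2, 4)
              .reshape(n, ho, wo, c, ph * pw))
        self._idx = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        ph, pw = self.size
        n, h, w, c = self._xshape
        ho, wo = h // ph, w // pw
        dxr = np.zeros((n, ho, wo, c, ph * pw))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c))
        dx[:, :ho * ph, :wo * pw, :] = (
            dxr.reshape(n, ho, wo, c, ph, pw)
               .transpose(0, 1, 4, 2, 5, 3)
               .reshape(n, ho * ph, wo * pw, c))
        return dx


class AvgPool2D(_Pool):
    def forward(self, x, training=False, rng=None):
        ph, pw = self.size
        n, h, w, c, ho, wo = self._check(x)
        self._xshape = x.shape
        xr = x[:, :ho * ph, :wo * pw, :].reshape(n, ho, ph, wo, pw, c)
        return xr.mean(axis=(2, 4))

    def backward(self, dy):
        ph, pw = self.size
        n, h, w, c = self._xshape
        ho, wo = h // ph, w // pw
        dx = np.zeros((n, h, w, c))
        spread = np.repeat(np.repeat(dy, ph, axis=1), pw, axis=2)
        dx[:, :ho * ph, :wo * pw, :] = spread / (ph * pw)
        return dx


class Sequential:
    """Ordered layer stack with parameter and input gradients."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass; returns shape (N, 1)."""
        return self.forward(np.asarray(x, dtype=float), training=False)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(sum of scalar outputs)/dx in eval mode, shaped like x."""
        x = np.asarray(x, dtype=float)
        out = self.forward(x, training=False)
        return self.backward(np.ones_like(out))

    def l2_loss(self) -> float:
        return sum(l.l2_loss() for l in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            p[...] = w

    def get_state(self) -> dict:
        """Weights plus batch-norm running statistics."""
        state = {"weights": self.get_weights(), "bn": []}
        for l in self.layers:
            if isinstance(l, BatchNorm):
                state["bn"].append((l.running_mean.copy(),
                                    l.running_var.copy()))
        return state

    def set_state(self, state: dict) -> None:
        self.set_weights(state["weights"])
        bn_layers = [l for l in self.layers if isinstance(l, BatchNorm)]
        for l, (rm, rv) in zip(bn_layers, state["bn"]):
            l.running_mean = rm.copy()
            l.running_var = rv.copy()


class Adam:
    """Adam with externally scheduled learning rate."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
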