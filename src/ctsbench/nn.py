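"""A compact CPU neural-network engine for small sequence CNNs.

Implements exactly the pieces the accessibility models need — 1-D "same"
convolution (im2col), ReLU, non-overlapping max pooling, dense layers, a
softplus output head, Poisson regression loss, and Adam — with manual
backpropagation in numpy. Gradients with respect to the input are exposed
(needed for gradient*input attribution). Everything is deterministic given
the initialization seed and single-threaded BLAS.

Layouts: sequence activations are (batch, channels, length) float32; dense
activations are (batch, features).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-8


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover - interface

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class BatchNorm(Layer):
    """Batch normalization over (batch, length) per channel for (B, C, L)
    activations, or over the batch per feature for (B, F) activations.
    Evaluation mode uses exponential running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=np.float32)
        self.beta = np.zeros(n_features, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    @staticmethod
    def _axes(x: np.ndarray) -> tuple:
        return (0, 2) if x.ndim == 3 else (0,)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x, train=False):
        axes = self._axes(x)
        self._train = train
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        self._std = std
        self._xhat = (x - self._expand(mean, x.ndim)) / self._expand(std, x.ndim)
        return self._expand(self.gamma, x.ndim) * self._xhat + self._expand(self.beta, x.ndim)

    def backward(self, grad):
        axes = self._axes(grad)
        ndim = grad.ndim
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        scale = self._expand(self.gamma / self._std, ndim)
        if not self._train:
            return grad * scale
        n = grad.size // grad.shape[1]
        mean_dy = self._expand(grad.mean(axis=axes), ndim)
        mean_dy_xhat = self._expand((grad * self._xhat).mean(axis=axes), ndim)
        return scale * (grad - mean_dy - self._xhat * mean_dy_xhat)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Conv1d(Layer):
    """Same-padded 1-D convolution; kernel width must be odd."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same padding")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, (c_out, c_in * kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None
        self.need_input_grad = True   # first layer may skip its input gradient

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, L = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        # (B, C, L, k) -> (B*L, C*k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C * self.kernel)
        self._cols, self._in_shape = cols, (B, C, L)
        y = cols @ self.W.T + self.b
        return np.ascontiguousarray(y.reshape(B, L, self.c_out).transpose(0, 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        k, pad = self.kernel, self.kernel // 2
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * L, self.c_out)
        self.dW[...] = g.T @ self._cols
        self.db[...] = g.sum(axis=0)
        if not self.need_input_grad:
            return None
        dcols = (g @ self.W).reshape(B, L, C, k)
        dxp = np.zeros((B, C, L + 2 * pad), dtype=grad.dtype)
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + L]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False):
        B, C, L = x.shape
        if self.pool == 1:
            self._passthrough = True
            return x
        self._passthrough = False
        Lp = L // self.pool
        xv = x[:, :, :Lp * self.pool].reshape(B, C, Lp, self.pool)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = (B, C, L)
        return np.take_along_axis(xv, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, grad):
        if self._passthrough:
            return grad
        B, C, L = self._in_shape
        Lp = grad.shape[2]
        dxv = np.zeros((B, C, Lp, self.pool), dtype=grad.dtype)
        np.put_along_axis(dxv, self._argmax[..., None], grad[..., None], axis=3)
        dx = np.zeros((B, C, L), dtype=grad.dtype)
        dx[:, :, :Lp * self.pool] = dxv.reshape(B, C, Lp * self.pool)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Softplus(Layer):
    """Strictly positive output head: y = log(1 + exp(x))."""

    def forward(self, x, train=False):
        self._x = x
        return np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))

    def backward(self, grad):
        return grad / (1.0 + np.exp(-self._x))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Propagate loss gradient; returns the gradient w.r.t. the input."""
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def poisson_loss(yhat: np.ndarray, y: np.ndarray) -> float:
    """Poisson regression deviance (up to y-only terms): mean(yhat - y log yhat)."""
    if (yhat <= 0).any():
        raise ValueError("Poisson loss requires strictly positive predictions")
    return float(np.mean(yhat - y * np.log(yhat + EPS)))


def poisson_loss_grad(yhat: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (1.0 - y / (yhat + EPS)) / yhat.size


def inverse_softplus(y: float) -> float:
    """x such that softplus(x) = y (for positive-head bias initialization)."""
    if y > 30:
        return float(y)
    return float(np.log(np.expm1(max(y, 1e-6))))
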