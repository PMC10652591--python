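"""A minimal numpy feed-forward neural-network engine.

Implements exactly the pieces the pipeline's models need — dense and 1-D
convolutional layers, relu/elu/tanh/linear activations, dropout, max/average/
global-average pooling, softmax cross-entropy and mean-squared-error
objectives, and Adam/RMSprop optimizers — with a single-integer seeding
contract covering weight initialization, batch shuffling and dropout masks.

Reproducibility is same-machine: identical seed, data and architecture give
bit-identical training runs in a single-threaded numpy process.

Shapes: dense layers operate on (batch, features); convolutional layers on
(batch, length, channels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

ACTIVATIONS = ("relu", "elu", "linear", "tanh")


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "elu":
        return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))
    if name == "tanh":
        return np.tanh(x)
    if name == "linear":
        return x
    raise ValueError(f"unknown activation: {name!r}")


def _act_grad(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (x > 0).astype(x.dtype)
    if name == "elu":
        return np.where(x > 0, 1.0, y + 1.0)
    if name == "tanh":
        return 1.0 - y * y
    if name == "linear":
        return np.ones_like(x)
    raise ValueError(f"unknown activation: {name!r}")


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer with optional fused activation.

    ``init='glorot_uniform'`` is the default; ``init='uniform'`` draws from
    U(-0.05, 0.05) (the classic uniform kernel initializer, used for the
    autoencoder bottleneck).
    """

    def __init__(self, n_in, n_out, activation="linear", init="glorot_uniform", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if init == "glorot_uniform":
            limit = math.sqrt(6.0 / (n_in + n_out))
        elif init == "uniform":
            limit = 0.05
        else:
            raise ValueError(f"unknown initializer: {init!r}")
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        self._x = x
        self._z = x @ self.W + self.b
        self._y = _act(self.activation, self._z)
        return self._y

    def backward(self, grad):
        grad = grad * _act_grad(self.activation, self._z, self._y)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """Valid-padding 1-D convolution, (batch, length, channels_in) ->
    (batch, length - k + 1, filters)."""

    def __init__(self, channels_in, filters, kernel_size, activation="linear",
                 init="glorot_uniform", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * channels_in
        fan_out = kernel_size * filters
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(kernel_size, channels_in, filters))
        self.b = np.zeros(filters)
        self.k = kernel_size
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool):
        self._x = x
        B, L, C = x.shape
        Lo = L - self.k + 1
        if Lo < 1:
            raise ValueError(
                f"sequence length {L} too short for kernel size {self.k}"
            )
        z = np.broadcast_to(self.b, (B, Lo, self.W.shape[2])).copy()
        for dk in range(self.k):
            z += x[:, dk:dk + Lo, :] @ self.W[dk]
        self._z = z
        self._y = _act(self.activation, z)
        return self._y

    def backward(self, grad):
        grad = grad * _act_grad(self.activation, self._z, self._y)
        x = self._x
        B, L, C = x.shape
        Lo = grad.shape[1]
        dx = np.zeros_like(x)
        for dk in range(self.k):
            self.grads[0][dk][...] = np.einsum("blc,blf->cf", x[:, dk:dk + Lo, :], grad)
            dx[:, dk:dk + Lo, :] += grad @ self.W[dk].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        return dx


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the sequence axis (trailing
    remainder dropped)."""

    def __init__(self, pool_size=2):
        super().__init__()
        self.p = pool_size

    def forward(self, x, train: bool):
        B, L, C = x.shape
        Lo = L // self.p
        if Lo < 1:
            raise ValueError(f"sequence length {L} too short for pool size {self.p}")
        self._in_shape = x.shape
        xr = x[:, : Lo * self.p, :].reshape(B, Lo, self.p, C)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        B, L, C = self._in_shape
        Lo = L // self.p
        dx = np.zeros((B, Lo, self.p, C), dtype=grad.dtype)
        bi, li, ci = np.ogrid[:B, :Lo, :C]
        dx[bi, li, self._argmax, ci] = grad
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        out[:, : Lo * self.p, :] = dx.reshape(B, Lo * self.p, C)
        return out


class GlobalAvgPool1D(Layer):
    def forward(self, x, train: bool):
        self._in_shape = x.shape
        return x.mean(axis=1)

    def backward(self, grad):
        B, L, C = self._in_shape
        return np.repeat(grad[:, None, :], L, axis=1) / L


class Flatten(Layer):
    def forward(self, x, train: bool):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape

    def forward(self, x, train: bool):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, grad):
        return grad.reshape(self._in_shape)


# ---------------------------------------------------------------------------
# optimizers


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict = {}

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m, v = self.state.setdefault(i, (np.zeros_like(p), np.zeros_like(p)))
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop:
    def __init__(self, lr=1e-3, rho=0.9, eps=1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.state: dict = {}

    def step(self, params, grads):
        for i, (p, g) in enumerate(zip(params, grads)):
            v = self.state.setdefault(i, np.zeros_like(p))
            v[...] = self.rho * v + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, lr: float):
    if name == "adam":
        return Adam(lr=lr)
    if name == "rmsprop":
        return RMSprop(lr=lr)
    raise ValueError(f"unknown optimizer: {name!r}")


# ---------------------------------------------------------------------------
# model


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    """A plain layer stack trained by mini-batch gradient descent.

    ``loss`` is ``"mse"`` (mean over batch and output dimensions) or
    ``"softmax_ce"`` (the final layer must emit logits; probabilities are
    produced by :meth:`predict_proba`).
    """

    def __init__(self, layers, loss="mse", optimizer="adam", lr=1e-3, rng=None):
        self.layers = layers
        self.loss = loss
        self.optimizer = make_optimizer(optimizer, lr)
        self.rng = rng or np.random.default_rng()

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _loss_and_grad(self, out, y):
        B = out.shape[0]
        if self.loss == "mse":
            diff = out - y
            return float((diff * diff).mean()), 2.0 * diff / diff.size
        if self.loss == "softmax_ce":
            p = softmax(out)
            eps = 1e-12
            loss = float(-(y * np.log(p + eps)).sum() / B)
            return loss, (p - y) / B
        raise ValueError(f"unknown loss: {self.loss!r}")

    def evaluate(self, x, y) -> float:
        out = self.forward(x, train=False)
        return self._loss_and_grad(out, y)[0]

    def fit(self, x, y, epochs, batch_size, shuffle=True, on_epoch=None):
        """Train in place; returns the per-epoch mean training loss."""
        n = x.shape[0]
        history = []
        for epoch in range(epochs):
            idx = self.rng.permutation(n) if shuffle else np.arange(n)
            losses = []
            for start in range(0, n, batch_size):
                batch = idx[start:start + batch_size]
                out = self.forward(x[batch], train=True)
                loss, grad = self._loss_and_grad(out, y[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self.optimizer.step(self.params, self.grads)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if on_epoch is not None:
                on_epoch(epoch, history[-1])
        return history

    def predict(self, x):
        return self.forward(x, train=False)

    def predict_proba(self, x):
        if self.loss != "softmax_ce":
            raise ValueError("predict_proba requires a softmax cross-entropy model")
        return softmax(self.forward(x, train=False))

    def weights_checksum(self) -> str:
        """Digest of all parameters; used to assert no-refit contracts."""
        import hashlib

        h = hashlib.sha256()
        for p in self.params:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()
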