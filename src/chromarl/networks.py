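"""Minimal NumPy neural networks for the control policies.

Implements exactly what the agent architecture needs - 1D convolutions over
the observation time window, dense layers, ReLU/tanh activations and the Adam
optimizer - with explicit forward/backward passes. Single-threaded NumPy
keeps training bit-reproducible under a fixed seed.

Observation tensors enter as (batch, window, features) and are treated as
1-D sequences with the features as channels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "Dense", "ReLU", "Tanh", "Flatten", "Sequential",
           "Adam", "ActorTCN", "CriticTCN"]


class Layer:
    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution, stride 1.

    Input (B, C_in, T) -> output (B, C_out, T - k + 1).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))   # He initialisation (ReLU follows)
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, T = x.shape
        k = self.kernel
        t_out = T - k + 1
        cols = np.empty((B, t_out, C * k))
        for j in range(k):
            cols[:, :, j * C:(j + 1) * C] = x[:, :, j:j + t_out].transpose(0, 2, 1)
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)                       # (B, T_out, C_in*k)
        out = self._cols @ self.W.T + self.b               # (B, T_out, C_out)
        return out.transpose(0, 2, 1)                      # (B, C_out, T_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.transpose(0, 2, 1)                         # (B, T_out, C_out)
        B, t_out, _ = dy.shape
        self.dW = np.tensordot(dy, self._cols, axes=([0, 1], [0, 1]))
        self.db = dy.sum(axis=(0, 1))
        dcols = dy @ self.W                                # (B, T_out, C_in*k)
        _, C, T = self._x_shape
        dx = np.zeros(self._x_shape)
        k = self.kernel
        for j in range(k):
            dx[:, :, j:j + t_out] += dcols[:, :, j * C:(j + 1) * C].transpose(0, 2, 1)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def _tcn_encoder(n_features: int, window: int, conv_filters: tuple,
                 kernel: int, rng: np.random.Generator):
    """Two conv + ReLU blocks followed by a flatten; returns (module, out_dim)."""
    f1, f2 = conv_filters
    t_out = window - 2 * (kernel - 1)
    if t_out < 1:
        raise ValueError("observation window too short for the conv stack")
    enc = Sequential([
        Conv1D(n_features, f1, kernel, rng), ReLU(),
        Conv1D(f1, f2, kernel, rng), ReLU(),
        Flatten(),
    ])
    return enc, f2 * t_out


class ActorTCN:
    """Policy network: (B, window, features) -> actions in [-1, 1]^4."""

    def __init__(self, n_features: int, window: int, action_dim: int,
                 rng: np.random.Generator, conv_filters=(128, 64),
                 fc_units: int = 300, kernel: int = 3):
        self.encoder, flat = _tcn_encoder(n_features, window, conv_filters,
                                          kernel, rng)
        self.head = Sequential([
            Dense(flat, fc_units, rng), ReLU(),
            Dense(fc_units, action_dim, rng, scale=1e-3), Tanh(),
        ])

    def forward(self, obs: np.ndarray) -> np.ndarray:
        x = np.asarray(obs, dtype=float).transpose(0, 2, 1)  # channels first
        return self.head.forward(self.encoder.forward(x))

    def backward(self, d_action: np.ndarray) -> None:
        self.encoder.backward(self.head.backward(d_action))

    def params(self):
        return self.encoder.params() + self.head.params()

    def grads(self):
        return self.encoder.grads() + self.head.grads()


class CriticTCN:
    """Q network: observation window + action -> scalar value.

    The flattened convolutional embedding of the state is concatenated with
    the action vector before the fully connected head.
    """

    def __init__(self, n_features: int, window: int, action_dim: int,
                 rng: np.random.Generator, conv_filters=(128, 64),
                 fc_units: int = 300, kernel: int = 3):
        self.encoder, flat = _tcn_encoder(n_features, window, conv_filters,
                                          kernel, rng)
        self.action_dim = action_dim
        self.head = Sequential([
            Dense(flat + action_dim, fc_units, rng), ReLU(),
            Dense(fc_units, 1, rng, scale=1e-3),
        ])

    def forward(self, obs: np.ndarray, action: np.ndarray) -> np.ndarray:
        x = np.asarray(obs, dtype=float).transpose(0, 2, 1)
        z = self.encoder.forward(x)
        self._split = z.shape[1]
        h = np.concatenate([z, action], axis=1)
        return self.head.forward(h)[:, 0]

    def backward(self, d_q: np.ndarray) -> np.ndarray:
        """Backpropagate dL/dQ (shape (B,)); returns dL/d(action)."""
        dh = self.head.backward(d_q[:, None])
        dz, da = dh[:, :self._split], dh[:, self._split:]
        self.encoder.backward(dz)
        return da

    def params(self):
        return self.encoder.params() + self.head.params()

    def grads(self):
        return self.encoder.grads() + self.head.grads()


class Adam:
    """Adaptive-moment stochastic gradient descent over a parameter list."""

    def __init__(self, params: list, lr: float = 4e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def copy_weights(src, dst) -> None:
    for ps, pd in zip(src.params(), dst.params()):
        pd[...] = ps


def polyak_update(src, dst, tau: float) -> None:
    """Move target weights toward online weights: p_t += tau (p - p_t)."""
    for ps, pd in zip(src.params(), dst.params()):
        pd += tau * (ps - pd)


def get_weights(net) -> list:
    return [p.copy() for p in net.params()]


def set_weights(net, weights: list) -> None:
    for p, w in zip(net.params(), weights):
        p[...] = w
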