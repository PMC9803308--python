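"""Small neural-network primitives shared by the auto-encoder and the delineator.

Plain numpy: forward passes, analytic gradients, Glorot initialisation and an
Adam optimiser. Everything is seeded explicitly; no global random state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "activation",
    "activation_grad",
    "glorot_uniform",
    "softmax",
    "Adam",
]


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x, y):
    return (x > 0.0).astype(x.dtype)


def _sigmoid(x):
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sigmoid_grad(x, y):
    return y * (1.0 - y)


def _tanh_grad(x, y):
    return 1.0 - y * y


def _identity(x):
    return x


def _identity_grad(x, y):
    return np.ones_like(x)


# name -> (f, df) where df takes (pre-activation x, output y)
ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "tanh": (np.tanh, _tanh_grad),
    "identity": (_identity, _identity_grad),
}


def activation(name: str):
    try:
        return ACTIVATIONS[name][0]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; known: {sorted(ACTIVATIONS)}"
        ) from None


def activation_grad(name: str):
    try:
        return ACTIVATIONS[name][1]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; known: {sorted(ACTIVATIONS)}"
        ) from None


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimiser over a flat dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
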