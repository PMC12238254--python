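"""Minimal dense neural-network primitives on numpy.

Small multilayer perceptrons with explicit forward caches and hand-written
backward passes, plus an Adam optimizer.  Everything is deterministic given
the generator used at initialisation; gradients are verified against finite
differences in the test suite.

Parameter layout: a list ``[W0, b0, W1, b1, ...]`` with ``W`` of shape
(fan_in, fan_out).  The final layer is linear; hidden layers use tanh or
relu.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

Params = List[np.ndarray]


def mlp_init(sizes: Sequence[int], rng: np.random.Generator,
             activation: str = "tanh") -> Params:
    """Xavier/He initialisation for an MLP with layer ``sizes``."""
    params: Params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        if activation == "relu":
            scale = np.sqrt(2.0 / fan_in)
        else:
            scale = np.sqrt(1.0 / fan_in)
        params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    return params


def _act(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "tanh":
        return np.tanh(z)
    if activation == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {activation!r}")


def _act_grad(z: np.ndarray, h: np.ndarray, activation: str) -> np.ndarray:
    if activation == "tanh":
        return 1.0 - h * h
    return (z > 0.0).astype(z.dtype)


def mlp_forward(params: Params, x: np.ndarray,
                activation: str = "tanh") -> Tuple[np.ndarray, list]:
    """Forward pass; returns (output, cache). ``x`` is (batch, fan_in)."""
    cache = []
    h = x
    n_layers = len(params) // 2
    for i in range(n_layers):
        W, b = params[2 * i], params[2 * i + 1]
        z = h @ W + b
        if i < n_layers - 1:
            a = _act(z, activation)
        else:
            a = z
        cache.append((h, z, a))
        h = a
    return h, cache


def mlp_backward(params: Params, cache: list, dout: np.ndarray,
                 activation: str = "tanh") -> Tuple[Params, np.ndarray]:
    """Backward pass; returns (grads matching params layout, dx)."""
    grads: Params = [None] * len(params)  # type: ignore[list-item]
    n_layers = len(params) // 2
    d = dout
    for i in reversed(range(n_layers)):
        h_in, z, a = cache[i]
        if i < n_layers - 1:
            d = d * _act_grad(z, a, activation)
        W = params[2 * i]
        grads[2 * i] = h_in.T @ d
        grads[2 * i + 1] = d.sum(axis=0)
        d = d @ W.T
    return grads, d


def zeros_like_params(params: Params) -> Params:
    return [np.zeros_like(p) for p in params]


def add_grads(acc: Params, grads: Params, scale: float = 1.0) -> None:
    for a, g in zip(acc, grads):
        a += scale * g


class Adam:
    """Adam over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params: Params, lr: float = 3e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = zeros_like_params(params)
        self.v = zeros_like_params(params)
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_vjp(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """d loss / d logits given d loss / d probs, for row-wise softmax."""
    inner = (p * dp).sum(axis=-1, keepdims=True)
    return p * (dp - inner)
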