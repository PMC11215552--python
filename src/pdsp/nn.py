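"""Minimal fully-connected network engine in numpy.

Implements exactly what the model architecture needs: affine layers, ReLU,
inverted dropout, analytic backpropagation, global-norm gradient clipping and
Adam.  Everything is deterministic given the generator passed in, which is
what makes bitwise-reproducible training and the finite-difference gradient
checks in the test suite possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class Layer:
    W: np.ndarray  # (fan_in, fan_out)
    b: np.ndarray  # (fan_out,)

    def copy(self) -> "Layer":
        return Layer(self.W.copy(), self.b.copy())


def init_mlp(dims: Sequence[int], rng: np.random.Generator) -> list[Layer]:
    """He-initialized stack for ReLU hidden layers; the last layer is linear
    and gets the smaller Glorot-style scale."""
    layers = []
    for k in range(len(dims) - 1):
        fan_in, fan_out = dims[k], dims[k + 1]
        last = k == len(dims) - 2
        scale = np.sqrt(1.0 / fan_in) if last else np.sqrt(2.0 / fan_in)
        W = rng.normal(0.0, scale, size=(fan_in, fan_out))
        layers.append(Layer(W, np.zeros(fan_out)))
    return layers


def mlp_forward(
    x: np.ndarray,
    layers: Sequence[Layer],
    dropout_after: Sequence[bool],
    rate: float,
    train: bool,
    rng: Optional[np.random.Generator] = None,
):
    """Forward pass; ReLU on every layer except the last.

    Returns (output, cache); the cache carries per-layer inputs,
    pre-activations and dropout masks for the matching backward pass.
    Dropout is inverted (scaled at train time, identity in eval mode).
    """
    cache = []
    h = x
    for k, layer in enumerate(layers):
        z = h @ layer.W + layer.b
        a = np.maximum(z, 0.0) if k < len(layers) - 1 else z
        mask = None
        if dropout_after[k] and train and rate > 0.0:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
            a = a * mask
        cache.append((h, z, mask))
        h = a
    return h, cache


def mlp_backward(
    grad_out: np.ndarray,
    layers: Sequence[Layer],
    cache,
) -> tuple[np.ndarray, list[Layer]]:
    """Backpropagate through :func:`mlp_forward`.

    Returns (gradient w.r.t. the input, per-layer parameter gradients).
    """
    grads = [Layer(np.empty_like(l.W), np.empty_like(l.b)) for l in layers]
    g = grad_out
    for k in range(len(layers) - 1, -1, -1):
        inp, z, mask = cache[k]
        if mask is not None:
            g = g * mask
        if k < len(layers) - 1:
            g = g * (z > 0.0)
        grads[k].W[...] = inp.T @ g
        grads[k].b[...] = g.sum(axis=0)
        g = g @ layers[k].W.T
    return g, grads


def clip_global_norm(grads: Sequence[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adam over a flat list of parameter arrays, updated in place.

    ``weight_decay`` is decoupled (applied directly to the parameters, not
    through the moment estimates).
    """

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)) without overflow."""
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
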