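"""Dense-network primitives with explicit backpropagation.

Every model in this package is a small multilayer perceptron trained
full-batch or with minibatches of a few hundred samples at most, so the
affine layers, the ReLU nonlinearity and the Adam optimiser are written
directly on numpy arrays.  Keeping the backward passes explicit also makes
the alternating optimisation used by the teacher (singular-value terms with
a frozen common space) straightforward to express.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_mlp",
    "mlp_forward",
    "mlp_backward",
    "Adam",
    "he_normal",
]


def he_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """He-initialised weight matrix for ReLU layers."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def init_mlp(widths: list[int], rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Initialise an MLP as a list of ``(W, b)`` pairs.

    ``widths`` chains input width through hidden widths to the output width;
    a ReLU follows every affine map (including the last, so embeddings are
    non-negative).
    """
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        layers.append((he_normal(rng, fan_in, fan_out), np.zeros(fan_out)))
    return layers


def mlp_forward(layers, x):
    """Forward pass; returns (output, caches) with ReLU after every layer.

    ``x`` is ``(S, widths[0])``.  Caches hold the layer inputs and
    pre-activations needed by :func:`mlp_backward`.
    """
    h = np.asarray(x, dtype=float)
    caches = []
    for W, b in layers:
        z = h @ W + b
        caches.append((h, z))
        h = np.maximum(z, 0.0)
    return h, caches


def mlp_backward(layers, caches, grad_out):
    """Backward pass matching :func:`mlp_forward`.

    Returns ``(param_grads, grad_input)`` where ``param_grads`` is a list of
    ``(dW, db)`` aligned with ``layers``.
    """
    grads = [None] * len(layers)
    g = np.asarray(grad_out, dtype=float)
    for i in range(len(layers) - 1, -1, -1):
        W, _b = layers[i]
        h_in, z = caches[i]
        g = g * (z > 0.0)
        grads[i] = (h_in.T @ g, g.sum(axis=0))
        g = g @ W.T
    return grads, g


class Adam:
    """Adam optimiser over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads, lr: float) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
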