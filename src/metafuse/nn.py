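"""Minimal fully connected network: ReLU hiddens, softmax output, Adam.

Plain-numpy implementation so that training is bit-deterministic for a given
seed on a single CPU: weight initialization and minibatch shuffling each draw
from generators spawned from the configured seed, and all arithmetic is
ordinary float64 numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ADAM_EPS = 1e-8


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLP:
    """Feedforward classifier with an embedding tap at the last hidden layer."""

    layer_sizes: list[int]  # [n_in, h1, ..., hk, n_classes]
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def init(cls, layer_sizes: list[int], seed: int) -> "MLP":
        """He-normal weight init, zero biases."""
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if any(s < 1 for s in layer_sizes):
            raise ValueError("all layer sizes must be >= 1")
        rng = np.random.default_rng(seed)
        weights, biases = [], []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            weights.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
            biases.append(np.zeros(n_out))
        return cls(list(layer_sizes), weights, biases)

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; last entry is the softmax output."""
        acts = [X]
        a = X
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = softmax(z) if li == len(self.weights) - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects {self.layer_sizes[0]}"
            )
        return self._forward(X)[-1]

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input has {X.shape[1]} features, network expects {self.layer_sizes[0]}"
            )
        return self._forward(X)[-2]

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 16,
        learning_rate: float = 0.001,
        beta_1: float = 0.9,
        beta_2: float = 0.999,
        seed: int = 0,
        shuffle: bool = True,
    ) -> "MLP":
        """Minimize mean categorical cross-entropy with Adam, in place."""
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if np.isnan(X).any():
            raise ValueError("NaN in training input")
        n = X.shape[0]
        rng = np.random.default_rng(seed)
        m_w = [np.zeros_like(W) for W in self.weights]
        v_w = [np.zeros_like(W) for W in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        t = 0
        for _ in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                acts = self._forward(X[idx])
                # softmax + cross-entropy gradient
                delta = (acts[-1] - Y[idx]) / len(idx)
                grads_w, grads_b = [], []
                for li in range(len(self.weights) - 1, -1, -1):
                    grads_w.append(acts[li].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if li > 0:
                        delta = (delta @ self.weights[li].T) * (acts[li] > 0)
                grads_w.reverse()
                grads_b.reverse()
                t += 1
                corr1 = 1.0 - beta_1**t
                corr2 = 1.0 - beta_2**t
                for li in range(len(self.weights)):
                    for param, grad, m, v in (
                        (self.weights[li], grads_w[li], m_w[li], v_w[li]),
                        (self.biases[li], grads_b[li], m_b[li], v_b[li]),
                    ):
                        m *= beta_1
                        m += (1 - beta_1) * grad
                        v *= beta_2
                        v += (1 - beta_2) * grad**2
                        param -= learning_rate * (m / corr1) / (np.sqrt(v / corr2) + _ADAM_EPS)
        return self

    def copy(self) -> "MLP":
        return MLP(
            list(self.layer_sizes),
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
        )
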