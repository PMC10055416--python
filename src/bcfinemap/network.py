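"""A small fully connected inference network, p = F(z; phi), in NumPy.

The network maps the m-vector of z-scores to the m-vector probability map
of the variational proposal. It is trained per locus from random
initialization, so the architecture is deliberately small: two hidden
layers with an elementwise nonlinearity and a sigmoid output squashed
into (0,1). Gradients are hand-coded (the loss gradient w.r.t. the
network output has a closed form upstream, so full autograd is not
needed), and parameters are updated with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .concrete import CLAMP

__all__ = ["InferenceNetConfig", "InferenceNet", "Adam"]

_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0.0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "softplus": (
        lambda x: np.logaddexp(0.0, x),
        expit,
    ),
}


@dataclass(frozen=True)
class InferenceNetConfig:
    """Architecture of the inference network."""

    hidden_sizes: tuple[int, ...] = (256, 256)
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {sorted(_ACTIVATIONS)}"
            )


class InferenceNet:
    """Fully connected z -> hidden -> ... -> m network with sigmoid output."""

    def __init__(self, m: int, config: InferenceNetConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.config = config or InferenceNetConfig()
        self.m = m
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        sizes = (m, *self.config.hidden_sizes, m)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # Glorot-style scale keeps pre-sigmoid outputs near 0 => p near 0.5
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._act, self._dact = _ACTIVATIONS[self.config.activation]
        self._cache: list[np.ndarray] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, z: np.ndarray) -> np.ndarray:
        """Probability map for the locus, clamped into (0, 1).

        Deterministic given the network state; caches pre-activations for
        :meth:`backward`.
        """
        z = np.asarray(z, dtype=float).ravel()
        if z.shape[0] != self.m:
            raise ValueError(f"z length {z.shape[0]} does not match network m={self.m}")
        pre_acts = []
        h = z
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = h @ W + b
            pre_acts.append((h, a))
            h = self._act(a)
        a_out = h @ self.weights[-1] + self.biases[-1]
        pre_acts.append((h, a_out))
        p_raw = expit(a_out)
        self._cache = pre_acts
        self._p_raw = p_raw
        return np.clip(p_raw, CLAMP, 1.0 - CLAMP)

    def backward(self, grad_p: np.ndarray) -> list[np.ndarray]:
        """Backpropagate d loss/d p to parameter gradients.

        The output clamp is a hard gate: coordinates pinned at the clamp
        bounds pass no gradient.
        """
        if self._cache is None:
            raise RuntimeError("call forward before backward")
        p = self._p_raw
        inside = (p > CLAMP) & (p < 1.0 - CLAMP)
        delta = grad_p * p * (1.0 - p) * inside  # sigmoid' = p(1-p)
        grads_W: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore[list-item]
        for layer in range(len(self.weights) - 1, -1, -1):
            h_in, a = self._cache[layer]
            grads_W[layer] = np.outer(h_in, delta)
            grads_b[layer] = delta.copy()
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * self._dact(self._cache[layer - 1][1])
        return grads_W + grads_b


@dataclass
class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    step_size: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, mom, vel in zip(params, grads, self._m, self._v):
            mom *= self.beta1
            mom += (1.0 - self.beta1) * g
            vel *= self.beta2
            vel += (1.0 - self.beta2) * g * g
            p -= self.step_size * (mom / b1t) / (np.sqrt(vel / b2t) + self.eps)
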