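"""The binary concrete (relaxed Bernoulli) distribution.

A binary concrete variable with probability-map parameter p and
temperature lam lives on (0,1) and concentrates at {0,1} as lam -> 0,
recovering a Bernoulli(p). Its two properties that matter here:
P(c > 1/2) = p for every temperature, and the reparameterized sampler

    c = sigmoid( (logit(u) + logit(p)) / lam ),   u ~ Uniform(0,1),

is differentiable in p, giving low-variance pathwise gradients.

The KL divergence between two binary concrete distributions has no closed
form; in the small-temperature regime both behave like Bernoullis and the
Bernoulli KL is used instead (see :func:`kl_to_prior`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, rel_entr, logit

from .data import PriorConfig

__all__ = [
    "BinaryConcreteParams",
    "sample",
    "sample_grad_p",
    "log_density",
    "kl_to_prior",
    "kl_to_prior_grad",
    "CLAMP",
]

CLAMP = 1e-6  # probability maps are kept this far from {0, 1}


def clamp_p(p: np.ndarray) -> np.ndarray:
    """Clamp a probability map to [CLAMP, 1-CLAMP] so logits stay finite."""
    return np.clip(np.asarray(p, dtype=float), CLAMP, 1.0 - CLAMP)


@dataclass(frozen=True)
class BinaryConcreteParams:
    """Probability map p in (0,1)^m and relaxation temperature lam > 0."""

    p: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", clamp_p(np.ravel(self.p)))
        if not self.lam > 0:
            raise ValueError("temperature lam must be positive")


def _check_u(u: np.ndarray, m: int) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != m:
        raise ValueError(f"uniform draws have last dimension {u.shape[-1]}, expected {m}")
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("uniform draws must lie strictly inside (0, 1)")
    return u


def sample(
    params: BinaryConcreteParams,
    u: np.ndarray | None = None,
    *,
    size: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw reparameterized binary concrete samples.

    Either pass explicit uniform draws ``u`` (any leading shape, last axis
    of length m) or a ``size`` plus seeded ``rng``. Identical draws give
    identical samples.
    """
    m = params.p.shape[0]
    if u is None:
        if size is None:
            raise ValueError("provide either u or size")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        # open-interval uniforms: nudge away from exact 0 (0 has measure ~2^-53)
        u = gen.random((size, m))
        u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    u = _check_u(u, m)
    return expit((logit(u) + logit(params.p)) / params.lam)


def sample_grad_p(params: BinaryConcreteParams, c: np.ndarray) -> np.ndarray:
    """dc/dp of the sampler, evaluated at already-drawn samples ``c``.

    From c = sigmoid((logit(u) + logit(p))/lam):
    dc/dp = c(1-c) / (lam * p(1-p)), elementwise, independent of u.
    """
    p = params.p
    return c * (1.0 - c) / (params.lam * p * (1.0 - p))


def log_density(params: BinaryConcreteParams, c: np.ndarray) -> float:
    """Log joint density of independent binary concrete coordinates.

    The per-coordinate density is
    lam*p*(1-p) * c^(-lam-1) (1-c)^(-lam-1) / (p*c^-lam + (1-p)*(1-c)^-lam)^2,
    evaluated in log space with a two-term logsumexp for the denominator.
    """
    c = np.asarray(c, dtype=float).ravel()
    if c.shape[0] != params.p.shape[0]:
        raise ValueError("c length does not match probability map")
    if np.any(c <= 0.0) or np.any(c >= 1.0):
        raise ValueError("c must lie strictly inside (0, 1)")
    p, lam = params.p, params.lam
    log_c, log_1mc = np.log(c), np.log1p(-c)
    a = np.log(p) - lam * log_c
    b = np.log1p(-p) - lam * log_1mc
    hi = np.maximum(a, b)
    log_denom = hi + np.log(np.exp(a - hi) + np.exp(b - hi))
    terms = (
        np.log(lam)
        + np.log(p)
        + np.log1p(-p)
        - (lam + 1.0) * (log_c + log_1mc)
        - 2.0 * log_denom
    )
    return float(np.sum(terms))


def kl_to_prior(params: BinaryConcreteParams, prior: PriorConfig) -> float:
    """Bernoulli-limit KL divergence to the uniform-p0 prior.

    sum_i p_i log(p_i/p0) + (1-p_i) log((1-p_i)/(1-p0)); exact for the
    Bernoulli limits of both distributions, and the approximation the loss
    uses once the temperatures are annealed small.
    """
    p = params.p
    p0 = prior.p0
    kl = rel_entr(p, np.full_like(p, p0)) + rel_entr(1.0 - p, np.full_like(p, 1.0 - p0))
    return float(np.sum(kl))


def kl_to_prior_grad(params: BinaryConcreteParams, prior: PriorConfig) -> np.ndarray:
    """d kl_to_prior / d p_i = log(p_i/p0) - log((1-p_i)/(1-p0))."""
    p = params.p
    return np.log(p / prior.p0) - np.log((1.0 - p) / (1.0 - prior.p0))
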