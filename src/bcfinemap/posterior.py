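"""Posterior summaries: configuration weights, PIPs, credible sets.

The harvested configuration set stands in for the exponentially large
space of binary causal configurations. Each configuration b is reweighted
exactly,

    P(b | z, LD) ∝ N(z; 0, Sigma(b)) * p0^|b| * (1-p0)^(m-|b|),

normalized over the reduced set with a log-sum-exp guard. The posterior
inclusion probability of variant i sums the weights of configurations
that include i. Credible sets are built in two steps: greedy selection of
"key" variants by conditional probability of causality given the keys
already chosen, then, per key, accumulation of variants ranked by
conditional inclusion probability given the *other* keys until the target
coverage is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp

from .data import EffectPrior, PriorConfig, SummaryStats
from .likelihood import LikelihoodCache
from .trainer import ConfigurationSet

__all__ = [
    "CredibleSet",
    "FineMapResult",
    "config_posterior",
    "compute_pips",
    "credible_sets",
]

ConfigKey = tuple[int, ...]


@dataclass(frozen=True)
class CredibleSet:
    """A set of variant indices with its attained posterior mass.

    ``attained`` is the cumulative conditional inclusion probability when
    the set was closed; ``complete`` is False when the requested coverage
    could not be reached from the posterior (the set then holds the full
    remaining support).
    """

    key_variant: int
    variants: tuple[int, ...]
    attained: float
    complete: bool = True

    def __contains__(self, i: int) -> bool:
        return i in self.variants

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class FineMapResult:
    """Everything a fine-mapping run returns to the user."""

    pip: np.ndarray
    credible_sets: list[CredibleSet]
    config_posterior: dict[ConfigKey, float]
    variant_ids: list[str]
    diagnostics: dict = field(default_factory=dict)


def _as_supports(configs: ConfigurationSet | Iterable[ConfigKey]) -> list[ConfigKey]:
    if isinstance(configs, ConfigurationSet):
        return configs.supports
    return [tuple(sorted(int(i) for i in s)) for s in configs]


def config_posterior(
    configs: ConfigurationSet | Iterable[ConfigKey],
    stats: SummaryStats,
    prior: PriorConfig | None = None,
    effect_prior: EffectPrior | None = None,
    method: str = "auto",
) -> dict[ConfigKey, float]:
    """Normalized posterior over a reduced set of binary configurations.

    Keys are sorted tuples of causal indices; values sum to one.
    """
    supports = _as_supports(configs)
    if not supports:
        raise ValueError("configuration set is empty")
    prior = prior or PriorConfig.uniform(stats.m)
    effect_prior = effect_prior or EffectPrior()
    cache = LikelihoodCache(stats, effect_prior)
    m = stats.m
    log_p0, log_1mp0 = np.log(prior.p0), np.log1p(-prior.p0)
    log_w = np.empty(len(supports))
    for row, support in enumerate(supports):
        b = np.zeros(m)
        b[list(support)] = 1.0
        k = len(support)
        log_w[row] = cache.loglik(b, method=method) + k * log_p0 + (m - k) * log_1mp0
    log_w -= logsumexp(log_w)
    return {s: float(w) for s, w in zip(supports, np.exp(log_w))}


def compute_pips(posterior: Mapping[ConfigKey, float], m: int) -> np.ndarray:
    """PIP_i = sum of posterior weight over configurations including i."""
    pip = np.zeros(m)
    for support, w in posterior.items():
        for i in support:
            pip[i] += w
    return pip


def _conditional_inclusion(
    posterior: Mapping[ConfigKey, float], condition: frozenset[int], m: int
) -> tuple[np.ndarray, float]:
    """P(b_i = 1 | b_k = 1 for k in condition) for all i, plus the
    conditioning mass."""
    mass = 0.0
    incl = np.zeros(m)
    for support, w in posterior.items():
        s = set(support)
        if condition <= s:
            mass += w
            for i in s:
                incl[i] += w
    if mass > 0:
        incl /= mass
    return incl, mass


def credible_sets(
    posterior: Mapping[ConfigKey, float],
    stats: SummaryStats,
    coverage: float = 0.95,
    max_sets: int = 10,
    key_threshold: float = 0.5,
) -> list[CredibleSet]:
    """Two-step credible-set construction over a configuration posterior.

    Step 1 greedily picks key variants: the next key is the variant with
    the highest conditional probability of causality given the keys
    already selected; selection stops when that probability drops below
    ``key_threshold`` or ``max_sets`` keys are found. Step 2 builds one
    set per key by ranking variants on their conditional inclusion
    probability given the *other* keys and accumulating until the
    cumulative probability reaches ``coverage``. Ties are broken by
    larger |z|, then lower index.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    m = stats.m
    abs_z = np.abs(stats.z)

    keys: list[int] = []
    while len(keys) < max_sets:
        cond, mass = _conditional_inclusion(posterior, frozenset(keys), m)
        if mass <= 0:
            break
        cond[keys] = -np.inf  # already selected
        best = _argmax_tiebreak(cond, abs_z)
        if cond[best] < key_threshold:
            break
        keys.append(best)

    sets: list[CredibleSet] = []
    for key in keys:
        others = frozenset(k for k in keys if k != key)
        incl, mass = _conditional_inclusion(posterior, others, m)
        if mass <= 0:
            continue
        candidates = [i for i in range(m) if i not in others and incl[i] > 0]
        candidates.sort(key=lambda i: (-incl[i], -abs_z[i], i))
        chosen: list[int] = []
        cum = 0.0
        complete = False
        for i in candidates:
            chosen.append(i)
            cum += incl[i]
            if cum >= coverage - 1e-12:
                complete = True
                break
        sets.append(
            CredibleSet(
                key_variant=key,
                variants=tuple(chosen),
                attained=min(cum, 1.0),
                complete=complete,
            )
        )
    return sets


def _argmax_tiebreak(values: np.ndarray, abs_z: np.ndarray) -> int:
    """Index of the maximum; ties resolved by larger |z|, then lower index."""
    top = np.max(values)
    tied = np.flatnonzero(values >= top - 1e-15)
    if tied.size == 1:
        return int(tied[0])
    return int(min(tied, key=lambda i: (-abs_z[i], i)))
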