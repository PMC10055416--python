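"""Stochastic variational optimization for a single locus.

Each iteration: the inference network maps z to a probability map p,
L relaxed causal vectors are drawn from the binary concrete proposal,
each is support-pruned and binarized (the binary configurations are
harvested into a running set), the Monte Carlo variational loss

    L(phi) = -(1/L) sum_l log N(z; 0, Sigma(c_l)) + KL_Bernoulli(p || p0)

is evaluated, and one Adam step is taken on the network weights. The
temperature lam is annealed geometrically from lam_init to lam_final, at
which point the Bernoulli KL approximation is accurate. The harvested
configuration set is reweighted exactly afterwards (see
:mod:`bcfinemap.posterior`), so harvest multiplicities are diagnostics
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concrete import (
    BinaryConcreteParams,
    kl_to_prior,
    kl_to_prior_grad,
    sample,
    sample_grad_p,
)
from .data import EffectPrior, PriorConfig, SummaryStats
from .likelihood import LikelihoodCache
from .network import Adam, InferenceNet, InferenceNetConfig

__all__ = ["TrainConfig", "ConfigurationSet", "binarize", "prune_support", "loss", "fit"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters.

    iters
        Number of gradient iterations T.
    mc_samples
        Monte Carlo sample count L per iteration.
    step_size
        Adam step size.
    lam_init, lam_final
        Endpoints of the geometric temperature annealing schedule;
        lam_final = 0.01 keeps the Bernoulli KL approximation valid at
        convergence.
    support_threshold
        Entries of a sampled causal vector at or below this value are
        zeroed before likelihood evaluation.
    support_cap
        Maximum retained support per sample; the largest entries win,
        ties broken by lowest variant index.
    binarize_gamma
        Threshold for binarizing pruned causal vectors into harvested
        configurations.
    """

    iters: int = 2000
    mc_samples: int = 10
    step_size: float = 1e-3
    lam_init: float = 0.5
    lam_final: float = 0.01
    support_threshold: float = 0.01
    support_cap: int = 50
    binarize_gamma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iters <= 0 or self.mc_samples <= 0:
            raise ValueError("iters and mc_samples must be positive")
        if not self.lam_final <= self.lam_init:
            raise ValueError("lam_final must not exceed lam_init")
        if not 0.0 < self.support_threshold < self.binarize_gamma < 1.0:
            raise ValueError("need 0 < support_threshold < binarize_gamma < 1")
        if self.support_cap <= 0:
            raise ValueError("support_cap must be positive")

    def lam_schedule(self) -> np.ndarray:
        """Geometric annealing lam_t = lam_init * (lam_final/lam_init)^(t/(T-1))."""
        if self.iters == 1:
            return np.array([self.lam_final])
        t = np.arange(self.iters) / (self.iters - 1)
        return self.lam_init * (self.lam_final / self.lam_init) ** t


@dataclass
class ConfigurationSet:
    """Deduplicated harvested binary causal configurations.

    Configurations are keyed by their (sorted) support index tuple;
    ``counts`` records how often each was harvested. Posterior weights
    are *not* derived from counts — they come from exact reweighting of
    the reduced set.
    """

    m: int
    counts: dict[tuple[int, ...], int] = field(default_factory=dict)

    def add(self, b: np.ndarray) -> None:
        key = tuple(np.flatnonzero(b).tolist())
        self.counts[key] = self.counts.get(key, 0) + 1

    def add_support(self, support: tuple[int, ...]) -> None:
        self.counts[support] = self.counts.get(support, 0) + 1

    @property
    def supports(self) -> list[tuple[int, ...]]:
        return list(self.counts.keys())

    def configs(self) -> np.ndarray:
        """Dense 0/1 matrix of shape (n_configs, m)."""
        out = np.zeros((len(self.counts), self.m))
        for row, support in enumerate(self.counts):
            out[row, list(support)] = 1.0
        return out

    def __len__(self) -> int:
        return len(self.counts)

    def max_support_size(self) -> int:
        return max((len(s) for s in self.counts), default=0)


def binarize(c: np.ndarray, gamma: float) -> np.ndarray:
    """0/1 vector with b_i = 1 iff c_i > gamma (strict)."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    return (np.asarray(c, dtype=float) > gamma).astype(float)


def prune_support(c: np.ndarray, threshold: float, cap: int) -> np.ndarray:
    """Zero entries <= threshold; if more than ``cap`` survive, keep the
    ``cap`` largest (ties broken by lowest index)."""
    pruned = np.where(c > threshold, c, 0.0)
    support = np.flatnonzero(pruned)
    if support.size > cap:
        # stable argsort on -c ranks equal values by ascending index
        order = support[np.argsort(-pruned[support], kind="stable")]
        pruned_capped = np.zeros_like(pruned)
        keep = order[:cap]
        pruned_capped[keep] = pruned[keep]
        return pruned_capped
    return pruned


def loss(
    stats: SummaryStats,
    p: np.ndarray,
    lam: float,
    prior: PriorConfig,
    effect_prior: EffectPrior,
    u_draws: np.ndarray,
    train_config: TrainConfig | None = None,
    cache: LikelihoodCache | None = None,
    method: str = "auto",
) -> float:
    """Monte Carlo variational loss for a fixed probability map.

    Mirrors one iteration of :func:`fit` exactly (sampling from the given
    uniform draws, support pruning, likelihood averaging, Bernoulli KL)
    without taking a gradient step.
    """
    cfg = train_config or TrainConfig()
    cache = cache or LikelihoodCache(stats, effect_prior)
    params = BinaryConcreteParams(p, lam)
    C = sample(params, u_draws)
    if C.ndim == 1:
        C = C[np.newaxis, :]
    ll = 0.0
    for c_l in C:
        ll += cache.loglik(
            prune_support(c_l, cfg.support_threshold, cfg.support_cap), method=method
        )
    return -ll / C.shape[0] + kl_to_prior(params, prior)


def fit(
    stats: SummaryStats,
    net_config: InferenceNetConfig | None = None,
    train_config: TrainConfig | None = None,
    prior: PriorConfig | None = None,
    effect_prior: EffectPrior | None = None,
    method: str = "auto",
) -> tuple[np.ndarray, ConfigurationSet, np.ndarray]:
    """Run the per-locus optimization loop.

    Returns ``(probability_map, configuration_set, loss_trace)``. All
    randomness flows from ``train_config.seed``: identical seeds give a
    bit-identical configuration set, trace, and final map.
    """
    net_cfg = net_config or InferenceNetConfig()
    cfg = train_config or TrainConfig()
    prior = prior or PriorConfig.uniform(stats.m)
    effect_prior = effect_prior or EffectPrior()

    rng = np.random.default_rng(cfg.seed)
    net = InferenceNet(stats.m, net_cfg, rng=rng)
    opt = Adam(step_size=cfg.step_size)
    cache = LikelihoodCache(stats, effect_prior)
    harvested = ConfigurationSet(m=stats.m)
    # the reduced configuration set always contains the null (no-causal)
    # configuration: it anchors the reweighted posterior, so that under
    # weak data the mass can flow to "nothing is causal" instead of being
    # forced onto the smallest sampled support
    harvested.add_support(())
    lam_schedule = cfg.lam_schedule()
    trace = np.empty(cfg.iters)
    L = cfg.mc_samples
    tiny, eps = np.finfo(float).tiny, np.finfo(float).epsneg

    for t in range(cfg.iters):
        lam_t = float(lam_schedule[t])
        p = net.forward(stats.z)
        params = BinaryConcreteParams(p, lam_t)
        u = np.clip(rng.random((L, stats.m)), tiny, 1.0 - eps)
        C = sample(params, u)

        grad_p = kl_to_prior_grad(params, prior)
        loss_t = kl_to_prior(params, prior)
        ll_sum = 0.0
        for c_raw in C:
            c_l = prune_support(c_raw, cfg.support_threshold, cfg.support_cap)
            harvested.add(binarize(c_l, cfg.binarize_gamma))
            ll_sum += cache.loglik(c_l, method=method)
            # pathwise gradient; pruned coordinates are a hard gate
            g_c = cache.grad(c_l, method=method)
            grad_p -= (sample_grad_p(params, c_l) * g_c) / L
        loss_t -= ll_sum / L
        if not np.isfinite(loss_t):
            raise FloatingPointError(
                f"non-finite variational loss at iteration {t}; "
                "check the LD matrix conditioning or lower the step size"
            )
        trace[t] = loss_t
        opt.step(net.params, net.backward(grad_p))

    p_final = net.forward(stats.z)
    return p_final, harvested, trace
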