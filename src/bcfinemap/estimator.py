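"""The `FineMapper` estimator: one-call fine-mapping of a locus.

Wraps the variational optimization, configuration reweighting, PIP
computation, and credible-set construction behind a scikit-learn style
``fit`` interface with trailing-underscore fitted attributes, so the
estimator composes with sklearn tooling (``get_params``/``set_params``,
``clone``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import EffectPrior, PriorConfig, SummaryStats
from .network import InferenceNetConfig
from .posterior import (
    FineMapResult,
    compute_pips,
    config_posterior,
    credible_sets,
)
from .trainer import TrainConfig, fit as _fit_locus

__all__ = ["FineMapper", "finemap"]


class FineMapper(BaseEstimator):
    """Bayesian fine-mapping from GWAS summary statistics.

    Fits a binary concrete variational approximation to the posterior
    over causal configurations at a single locus, using a small neural
    inference network trained per locus. Produces posterior inclusion
    probabilities and credible sets.

    Parameters
    ----------
    sigma2 : float
        Prior variance scale of a standardized causal effect
        (n * sigma2 is the z-scale inflation per causal variant).
    ridge : float
        Diagonal stabilizer added to the LD matrix.
    p0 : float or None
        Prior inclusion probability; ``None`` means 1/m at fit time.
    iters, mc_samples, step_size, lam_init, lam_final : optimization
        hyper-parameters, see :class:`bcfinemap.trainer.TrainConfig`.
    support_threshold, support_cap, binarize_gamma : sampling/pruning
        constants of the harvest loop.
    coverage : float
        Target credible-set coverage.
    max_sets : int
        Maximum number of credible sets (key variants).
    key_threshold : float
        Minimum conditional probability for selecting another key variant.
    likelihood_method : {"auto", "dense", "lowrank"}
        Likelihood evaluation path.
    seed : int
        Seed for network initialization and Monte Carlo sampling.

    Attributes
    ----------
    pip_ : ndarray of shape (m,)
        Posterior inclusion probabilities.
    credible_sets_ : list of CredibleSet
    config_posterior_ : dict mapping support tuples to probabilities
    probability_map_ : ndarray of shape (m,)
        Final variational probability map p.
    loss_trace_ : ndarray of shape (iters,)
    result_ : FineMapResult

    Examples
    --------
    >>> mapper = FineMapper(iters=500, seed=7)
    >>> mapper.fit(z, ld, n=5000)           # doctest: +SKIP
    >>> mapper.pip_.argmax()                # doctest: +SKIP
    """

    def __init__(
        self,
        *,
        sigma2: float = 0.005,
        ridge: float = 1e-4,
        p0: float | None = None,
        lam0: float = 0.01,
        hidden_sizes: tuple[int, ...] = (256, 256),
        activation: str = "relu",
        iters: int = 2000,
        mc_samples: int = 10,
        step_size: float = 1e-3,
        lam_init: float = 0.5,
        lam_final: float = 0.01,
        support_threshold: float = 0.01,
        support_cap: int = 50,
        binarize_gamma: float = 0.1,
        coverage: float = 0.95,
        max_sets: int = 10,
        key_threshold: float = 0.5,
        likelihood_method: str = "auto",
        seed: int = 0,
    ):
        self.sigma2 = sigma2
        self.ridge = ridge
        self.p0 = p0
        self.lam0 = lam0
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.iters = iters
        self.mc_samples = mc_samples
        self.step_size = step_size
        self.lam_init = lam_init
        self.lam_final = lam_final
        self.support_threshold = support_threshold
        self.support_cap = support_cap
        self.binarize_gamma = binarize_gamma
        self.coverage = coverage
        self.max_sets = max_sets
        self.key_threshold = key_threshold
        self.likelihood_method = likelihood_method
        self.seed = seed

    # ------------------------------------------------------------------

    def _configs(self, m: int):
        prior = PriorConfig(p0=self.p0 if self.p0 is not None else 1.0 / m,
                            lam0=self.lam0)
        effect_prior = EffectPrior(sigma2=self.sigma2, ridge=self.ridge)
        net_cfg = InferenceNetConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            activation=self.activation,
            seed=self.seed,
        )
        train_cfg = TrainConfig(
            iters=self.iters,
            mc_samples=self.mc_samples,
            step_size=self.step_size,
            lam_init=self.lam_init,
            lam_final=self.lam_final,
            support_threshold=self.support_threshold,
            support_cap=self.support_cap,
            binarize_gamma=self.binarize_gamma,
            seed=self.seed,
        )
        return prior, effect_prior, net_cfg, train_cfg

    def fit(self, z, ld=None, *, n: int | None = None, variant_ids=None):
        """Fine-map one locus.

        Accepts either a :class:`SummaryStats` as the first argument, or
        ``(z, ld, n=...)`` arrays.
        """
        if isinstance(z, SummaryStats):
            stats = z
        else:
            if ld is None or n is None:
                raise ValueError("provide ld and n alongside a raw z vector")
            stats = SummaryStats(z=np.asarray(z, dtype=float), ld=np.asarray(ld, dtype=float),
                                 n=n, variant_ids=variant_ids)
        prior, effect_prior, net_cfg, train_cfg = self._configs(stats.m)

        p_map, harvested, trace = _fit_locus(
            stats, net_cfg, train_cfg, prior, effect_prior,
            method=self.likelihood_method,
        )
        posterior = config_posterior(
            harvested, stats, prior, effect_prior, method=self.likelihood_method
        )
        pip = compute_pips(posterior, stats.m)
        sets = credible_sets(
            posterior, stats,
            coverage=self.coverage, max_sets=self.max_sets,
            key_threshold=self.key_threshold,
        )

        self.stats_ = stats
        self.probability_map_ = p_map
        self.configs_ = harvested
        self.loss_trace_ = trace
        self.config_posterior_ = posterior
        self.pip_ = pip
        self.credible_sets_ = sets
        self.result_ = FineMapResult(
            pip=pip,
            credible_sets=sets,
            config_posterior=posterior,
            variant_ids=list(stats.variant_ids),
            diagnostics={
                "seed": self.seed,
                "iters": self.iters,
                "mc_samples": self.mc_samples,
                "lam_init": self.lam_init,
                "lam_final": self.lam_final,
                "sigma2": self.sigma2,
                "ridge": self.ridge,
                "p0": prior.p0,
                "binarize_gamma": self.binarize_gamma,
                "coverage": self.coverage,
                "n_configs": len(harvested),
                "final_loss": float(trace[-1]),
            },
        )
        return self

    def predict(self, z=None):
        """Return the fitted PIP vector (the per-variant causal score)."""
        if not hasattr(self, "pip_"):
            raise RuntimeError("FineMapper is not fitted yet")
        return self.pip_


def finemap(stats: SummaryStats, **params) -> FineMapResult:
    """Functional one-shot interface over :class:`FineMapper`."""
    return FineMapper(**params).fit(stats).result_
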