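"""Core data containers for summary-statistic fine-mapping.

A locus is described entirely by its GWAS summary data: the vector of
per-variant z-scores, the matching LD (Pearson correlation) matrix, and
the GWAS sample size. Effect-size and inclusion priors are small frozen
parameter bundles shared across modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SummaryStats", "EffectPrior", "PriorConfig"]

_SYM_TOL = 1e-6


@dataclass(frozen=True)
class SummaryStats:
    """GWAS summary data for one locus.

    Parameters
    ----------
    z : ndarray of shape (m,)
        Per-variant z-scores (effect size / standard error).
    ld : ndarray of shape (m, m)
        Pearson correlation matrix of the genotypes, diagonal 1.
    n : int
        GWAS sample size.
    variant_ids : list of str, optional
        Identifiers in file order; defaults to ``v0 .. v{m-1}``.
    """

    z: np.ndarray
    ld: np.ndarray
    n: int
    variant_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float).ravel()
        ld = np.asarray(self.ld, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "ld", ld)
        m = z.shape[0]
        if ld.ndim != 2 or ld.shape != (m, m):
            raise ValueError(
                f"LD matrix shape {ld.shape} does not match {m} z-scores"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("z-scores must be finite")
        if not np.all(np.isfinite(ld)):
            raise ValueError("LD matrix must be finite")
        if np.max(np.abs(ld - ld.T)) > _SYM_TOL:
            raise ValueError("LD matrix is not symmetric within 1e-6")
        if np.max(np.abs(np.diag(ld) - 1.0)) > _SYM_TOL:
            raise ValueError("LD matrix diagonal must equal 1 within 1e-6")
        if self.n <= 0 or int(self.n) != self.n:
            raise ValueError("sample size n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))
        if self.variant_ids is None:
            object.__setattr__(self, "variant_ids", [f"v{i}" for i in range(m)])
        elif len(self.variant_ids) != m:
            raise ValueError("variant_ids length does not match z")

    @property
    def m(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class EffectPrior:
    """Per-causal effect-size variance scale and LD ridge stabilizer.

    ``sigma2`` is the prior variance scale of a standardized causal effect,
    so that a causal variant inflates the z-score covariance by n·sigma2
    along its LD profile. The default 0.005 gives n·sigma2 = 25 at
    n = 5000, the conventional standardized-effect scale in
    summary-statistic fine-mapping. ``ridge`` is added to the LD diagonal
    before any factorization so rank-deficient matrices stay positive
    definite.
    """

    sigma2: float = 0.005
    ridge: float = 1e-4

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


@dataclass(frozen=True)
class PriorConfig:
    """Bernoulli-limit binary concrete prior over causal configurations.

    ``p0`` is the scalar prior inclusion probability (uniform across
    variants; 1/m is the conventional choice) and ``lam0`` the prior
    relaxation temperature.
    """

    p0: float = 0.01
    lam0: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly inside (0, 1)")
        if not self.lam0 > 0:
            raise ValueError("lam0 must be positive")

    @classmethod
    def uniform(cls, m: int, lam0: float = 0.01) -> "PriorConfig":
        """Prior with p0 = 1/m for a locus of m variants."""
        return cls(p0=1.0 / m, lam0=lam0)
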