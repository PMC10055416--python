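"""Self-contained GWAS simulation with block LD and a mixed-model trait.

Genotypes are generated from a latent-Gaussian haplotype model: within
each block of ``ld_block_size`` variants, a haplotype's latent variables
follow a first-order autocorrelation with parameter ``ld_rho`` (blocks
are independent), and each variant's minor allele is assigned to the
haplotypes whose latent value falls below the per-variant frequency
quantile. Thresholding is rank-based, so every simulated variant attains
its target minor-allele count exactly and the MAF floor is guaranteed by
construction. Genotype = sum of two independent haplotypes.

The quantitative trait follows a standard mixed linear model: d causal
variants carry Gaussian fixed effects, the remaining variants act through
a random effect with covariance X_NC X_NC'/(m-d), plus Gaussian noise.
The three components are rescaled by their empirical standard deviations
so the causal part explains exactly ``causal_var_share * omega2`` of the
phenotypic variance, the non-causal part ``(1-causal_var_share) * omega2``,
and the noise ``1 - omega2``.

Summary statistics mirror a real GWAS pipeline: per-variant simple OLS on
the *un-normalized* dosages gives effect estimates and standard errors,
z = beta_hat / se (clipped at |z| = 200), and the LD matrix is X'X/n on
column-standardized genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SummaryStats

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_phenotype",
    "compute_summary_stats",
    "simulate_study",
]

Z_CLIP = 200.0  # numeric-stability cap on |z|


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated locus.

    Defaults mirror the reference simulation design: n=5000 individuals,
    MAF floor 0.02, and a mixed-model trait with total genotype-explained
    variance ``omega2`` split between causal and non-causal variants by
    ``causal_var_share``.
    """

    n: int = 5000
    m: int = 1000
    d: int = 1
    omega2: float = 0.6
    causal_var_share: float = 0.9
    ld_block_size: int = 20
    ld_rho: float = 0.5
    maf_min: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.d < self.m:
            raise ValueError("need 1 <= d < m")
        if not 0.0 < self.omega2 < 1.0:
            raise ValueError("omega2 must lie in (0, 1)")
        if not 0.0 < self.causal_var_share <= 1.0:
            raise ValueError("causal_var_share must lie in (0, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if self.n <= 2:
            raise ValueError("need n > 2")


@dataclass(frozen=True)
class SimulatedStudy:
    """One simulated locus: genotypes, trait, truth, and summary stats."""

    genotypes: np.ndarray        # column-standardized, (n, m)
    raw_genotypes: np.ndarray    # integer dosages {0,1,2}, (n, m)
    phenotype: np.ndarray        # (n,), variance ~ 1
    causal_indices: np.ndarray   # (d,) sorted
    true_beta: np.ndarray        # (d,) effects on the standardized scale
    maf: np.ndarray              # (m,) target minor-allele frequencies
    stats: SummaryStats

    @property
    def truth(self) -> np.ndarray:
        """0/1 causal indicator of length m."""
        t = np.zeros(self.raw_genotypes.shape[1])
        t[self.causal_indices] = 1.0
        return t


def _latent_haplotypes(rng: np.random.Generator, n_hap: int, m: int,
                       block: int, rho: float) -> np.ndarray:
    """AR(1)-within-block latent Gaussians, shape (n_hap, m)."""
    eps = rng.standard_normal((n_hap, m))
    if rho == 0.0:
        return eps
    out = np.empty_like(eps)
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(m):
        if j % block == 0:
            out[:, j] = eps[:, j]
        else:
            out[:, j] = rho * out[:, j - 1] + scale * eps[:, j]
    return out


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw genotypes; returns ``(raw, standardized, maf)``.

    Minor-allele frequencies are uniform on [maf_min, 0.5]; each column's
    minor-allele count is met exactly by rank thresholding the latent
    values, so the realized MAF never falls below the floor.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, m = cfg.n, cfg.m
    maf = rng.uniform(cfg.maf_min, 0.5, size=m)
    latent = _latent_haplotypes(rng, 2 * n, m, cfg.ld_block_size, cfg.ld_rho)
    counts = np.maximum(
        np.ceil(2 * n * cfg.maf_min).astype(int),
        np.rint(2 * n * maf).astype(int),
    )
    alleles = np.zeros((2 * n, m), dtype=np.int8)
    for j in range(m):
        carriers = np.argpartition(latent[:, j], counts[j] - 1)[: counts[j]]
        alleles[carriers, j] = 1
    raw = (alleles[:n] + alleles[n:]).astype(float)
    std = standardize_genotypes(raw)
    return raw, std, maf


def standardize_genotypes(raw: np.ndarray) -> np.ndarray:
    """Column-center and scale to unit (population) variance."""
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        col = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"genotype column {col} has zero variance")
    return (raw - mean) / sd


def simulate_phenotype(
    genotypes: np.ndarray,
    causal_indices: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_components: bool = False,
):
    """Mixed-model trait; returns ``(phenotype, true_beta)``.

    ``genotypes`` must be column-standardized. Component variances are
    exact by construction: each of the causal, non-causal, and noise
    parts is rescaled by its own empirical standard deviation. With
    ``return_components`` the three rescaled components (causal,
    non-causal, noise) are returned as a third element.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, m = genotypes.shape
    causal_indices = np.asarray(causal_indices, dtype=int)
    d = causal_indices.size
    if d != cfg.d:
        raise ValueError("causal_indices size does not match cfg.d")

    beta = rng.standard_normal(d)
    g_c = genotypes[:, causal_indices] @ beta
    sd_c = g_c.std()
    if sd_c == 0:
        raise ValueError("degenerate draw: causal component has zero variance; retry with a new seed")

    noncausal = np.setdiff1d(np.arange(m), causal_indices)
    # g_NC ~ N(0, X_NC X_NC' / (m-d)), sampled through the genotypes
    g_nc = genotypes[:, noncausal] @ rng.standard_normal(noncausal.size) / np.sqrt(m - d)
    eps = rng.standard_normal(n)

    share, w2 = cfg.causal_var_share, cfg.omega2
    causal_part = np.sqrt(share * w2) / sd_c * g_c
    if share < 1.0:
        sd_nc = g_nc.std()
        if sd_nc == 0:
            raise ValueError("degenerate draw: non-causal component has zero variance; retry with a new seed")
        noncausal_part = np.sqrt((1.0 - share) * w2) / sd_nc * g_nc
    else:
        noncausal_part = np.zeros(n)
    noise_part = np.sqrt(1.0 - w2) / eps.std() * eps
    y = causal_part + noncausal_part + noise_part
    if return_components:
        return y, beta, (causal_part, noncausal_part, noise_part)
    return y, beta


def compute_summary_stats(
    raw_genotypes: np.ndarray,
    phenotype: np.ndarray,
    n: int | None = None,
    variant_ids: list[str] | None = None,
) -> SummaryStats:
    """Per-variant OLS summary statistics and the LD matrix.

    Simple regression with intercept per variant on the raw dosages:
    beta_hat = Sxy/Sxx, se^2 = (Syy - Sxy^2/Sxx) / ((n-2) Sxx),
    z = beta_hat/se, |z| clipped at 200. LD is X'X/n on standardized
    genotypes (unit diagonal by construction).
    """
    raw = np.asarray(raw_genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float).ravel()
    if raw.shape[0] != y.shape[0]:
        raise ValueError("genotype and phenotype sample sizes differ")
    n = n if n is not None else raw.shape[0]
    xc = raw - raw.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    if np.any(sxx == 0):
        col = int(np.flatnonzero(sxx == 0)[0])
        raise ValueError(f"genotype column {col} has zero variance")
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    beta_hat = sxy / sxx
    dof = raw.shape[0] - 2
    resid_var = np.maximum(syy - sxy**2 / sxx, 0.0) / dof
    with np.errstate(divide="ignore"):
        z = beta_hat / np.sqrt(resid_var / sxx)
    z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CLIP, neginf=-Z_CLIP),
                -Z_CLIP, Z_CLIP)
    std = xc / np.sqrt(sxx / raw.shape[0])
    ld = (std.T @ std) / raw.shape[0]
    np.fill_diagonal(ld, 1.0)
    return SummaryStats(z=z, ld=ld, n=n, variant_ids=variant_ids)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Full pipeline: genotypes -> trait -> summary statistics.

    Fully determined by ``cfg.seed``; re-running with the same config
    reproduces the study bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    raw, std, maf = simulate_genotypes(cfg, rng)
    causal = np.sort(rng.choice(cfg.m, size=cfg.d, replace=False))
    y, beta = simulate_phenotype(std, causal, cfg, rng)
    stats = compute_summary_stats(raw, y, n=cfg.n)
    return SimulatedStudy(
        genotypes=std,
        raw_genotypes=raw,
        phenotype=y,
        causal_indices=causal,
        true_beta=beta,
        maf=maf,
        stats=stats,
    )
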