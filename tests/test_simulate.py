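"""Synthetic genotype/phenotype generator and GWAS summary statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from bcfinemap.simulate import (
    SimulationConfig,
    compute_summary_stats,
    simulate_genotypes,
    simulate_phenotype,
    simulate_study,
)


def small_cfg(**kw):
    base = dict(n=2000, m=40, d=2, omega2=0.5, causal_var_share=0.7,
                ld_block_size=10, ld_rho=0.4, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_maf_floor_is_guaranteed(self):
        cfg = small_cfg(maf_min=0.05, seed=3)
        raw, _, _ = simulate_genotypes(cfg)
        maf = raw.mean(axis=0) / 2.0
        maf = np.minimum(maf, 1 - maf)
        assert np.all(maf >= cfg.maf_min - 1e-12)

    def test_standardized_columns_are_centered_unit_variance(self):
        _, std, _ = simulate_genotypes(small_cfg())
        np.testing.assert_allclose(std.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(std.var(axis=0), 1.0, atol=1e-8)

    def test_independence_limit_when_rho_zero(self):
        cfg = small_cfg(n=5000, m=30, ld_rho=0.0, seed=1)
        _, std, _ = simulate_genotypes(cfg)
        ld = std.T @ std / cfg.n
        off = np.abs(ld[~np.eye(cfg.m, dtype=bool)])
        assert off.mean() < 0.05

    def test_adjacent_ld_matches_latent_model_monte_carlo(self):
        """Empirical neighbor LD tracks a tetrachoric-style Monte Carlo
        oracle of the latent threshold model."""
        cfg = small_cfg(n=5000, m=20, ld_block_size=10, ld_rho=0.9, seed=7)
        raw, std, _ = simulate_genotypes(cfg)
        maf = raw.mean(axis=0) / 2.0
        maf = np.minimum(maf, 1 - maf)
        ld = std.T @ std / cfg.n

        oracle_rng = np.random.default_rng(999)
        x1 = oracle_rng.standard_normal(1_000_000)
        x2 = cfg.ld_rho * x1 + np.sqrt(1 - cfg.ld_rho**2) * oracle_rng.standard_normal(1_000_000)
        for j in range(cfg.m - 1):
            if (j + 1) % cfg.ld_block_size == 0:
                continue  # block boundary: independent by construction
            f1, f2 = maf[j], maf[j + 1]
            a1 = x1 < np.quantile(x1, f1)
            a2 = x2 < np.quantile(x2, f2)
            pred = np.corrcoef(a1, a2)[0, 1]
            assert ld[j, j + 1] == pytest.approx(pred, abs=0.1)

    def test_block_boundaries_are_uncorrelated(self):
        cfg = small_cfg(n=5000, m=30, ld_block_size=10, ld_rho=0.9, seed=2)
        _, std, _ = simulate_genotypes(cfg)
        ld = std.T @ std / cfg.n
        for j in (9, 19):
            assert abs(ld[j, j + 1]) < 0.1


class TestPhenotype:
    def test_total_variance_is_one(self):
        for seed in (0, 1):
            cfg = small_cfg(n=5000, seed=seed)
            study = simulate_study(cfg)
            assert study.phenotype.var() == pytest.approx(1.0, rel=0.05)

    def test_component_variances_exact_by_construction(self, rng):
        cfg = small_cfg(n=3000, seed=5)
        _, std, _ = simulate_genotypes(cfg)
        causal = np.array([3, 17])
        gen = np.random.default_rng(5)
        y, beta = simulate_phenotype(std, causal, cfg, gen)
        # replay the same draws to isolate the components
        gen2 = np.random.default_rng(5)
        beta2 = gen2.standard_normal(2)
        g_c = std[:, causal] @ beta2
        np.testing.assert_allclose(beta, beta2)
        share, w2 = cfg.causal_var_share, cfg.omega2
        scaled_c = np.sqrt(share * w2) / g_c.std() * g_c
        assert scaled_c.var() == pytest.approx(share * w2, rel=1e-10)

    def test_full_share_drops_noncausal_component(self):
        cfg = small_cfg(causal_var_share=1.0, n=1500, seed=9)
        study = simulate_study(cfg)
        # phenotype must be an exact linear combination of causal genotypes
        # plus noise: regressing out those columns leaves pure noise with
        # variance 1 - omega2
        X = study.genotypes[:, study.causal_indices]
        resid = study.phenotype - X @ np.linalg.lstsq(X, study.phenotype, rcond=None)[0]
        assert resid.var() == pytest.approx(1 - cfg.omega2, rel=0.01)

    def test_degenerate_causal_component_raises(self):
        # constant causal column -> causal component has zero variance
        cfg = small_cfg(d=1)
        rng = np.random.default_rng(0)
        geno = rng.standard_normal((100, 40))
        geno[:, 0] = 0.0
        with pytest.raises(ValueError, match="zero variance"):
            simulate_phenotype(geno, np.array([0]), cfg, rng)


class TestSummaryStats:
    def test_ols_matches_statsmodels_on_tiny_fixture(self):
        import statsmodels.api as sm

        raw = np.array(
            [[0, 1], [1, 0], [2, 2], [0, 1], [1, 0], [2, 1], [1, 2], [0, 0]],
            dtype=float,
        )
        y = np.array([0.2, -0.1, 1.4, 0.3, 0.0, 1.1, 0.9, -0.4])
        stats = compute_summary_stats(raw, y)
        for j in range(2):
            fitted = sm.OLS(y, sm.add_constant(raw[:, j])).fit()
            z_oracle = fitted.params[1] / fitted.bse[1]
            assert stats.z[j] == pytest.approx(z_oracle, abs=1e-10)

    def test_ld_diagonal_exactly_one(self):
        study = simulate_study(small_cfg())
        np.testing.assert_array_equal(np.diag(study.stats.ld), 1.0)

    def test_null_phenotype_gives_centered_z(self):
        cfg = small_cfg(n=4000, m=1000, d=1, ld_rho=0.0, ld_block_size=5, seed=11)
        raw, _, _ = simulate_genotypes(cfg)
        y = np.random.default_rng(12).standard_normal(cfg.n)
        stats = compute_summary_stats(raw, y)
        assert abs(stats.z.mean()) < 0.1
        # null z-scores are asymptotically standard normal
        assert stats.z.std() == pytest.approx(1.0, abs=0.1)

    def test_extreme_z_clipped(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=200).astype(float)
        y = 100.0 * x  # essentially deterministic relation -> huge z
        stats = compute_summary_stats(x[:, None], y)
        assert stats.z[0] == 200.0

    def test_zero_variance_column_named(self):
        raw = np.ones((50, 3))
        raw[:, 0] = np.random.default_rng(1).integers(0, 3, 50)
        raw[:, 2] = np.random.default_rng(2).integers(0, 3, 50)
        with pytest.raises(ValueError, match="column 1"):
            compute_summary_stats(raw, np.random.default_rng(3).standard_normal(50))

    def test_z_monotone_in_genotype_phenotype_correlation(self):
        study = simulate_study(small_cfg(n=3000, seed=13))
        corr = np.array([
            np.corrcoef(study.genotypes[:, j], study.phenotype)[0, 1]
            for j in range(study.genotypes.shape[1])
        ])
        assert sps.spearmanr(corr, study.stats.z).statistic == pytest.approx(1.0)


def test_same_seed_reproduces_study_bitwise():
    a = simulate_study(small_cfg(seed=21))
    b = simulate_study(small_cfg(seed=21))
    np.testing.assert_array_equal(a.raw_genotypes, b.raw_genotypes)
    np.testing.assert_array_equal(a.phenotype, b.phenotype)
    np.testing.assert_array_equal(a.stats.z, b.stats.z)
    np.testing.assert_array_equal(a.causal_indices, b.causal_indices)


def test_config_validation():
    with pytest.raises(ValueError):
        small_cfg(d=40)  # d >= m
    with pytest.raises(ValueError):
        small_cfg(omega2=1.0)
    with pytest.raises(ValueError):
        small_cfg(ld_rho=1.0)
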