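# Methods

This note records the model, the algorithmic and numerical choices, and
the limits of what the simulation study demonstrates.

## Generative model and likelihood

The locus is modeled by a linear trait y = Xβ + η on column-standardized
genotypes X, with a sparse prior on β: a causal variant's standardized
effect has variance σ², a non-causal variant's effect is (near) zero.
Marginalizing β gives the summary-statistic likelihood

    z ~ N(0, Σ),   Σ = Σ_X + Σ_X (n σ² diag(c)) Σ_X,

with Σ_X the LD matrix and c ∈ [0,1]^m the (possibly relaxed) causal
indicator. Two implementation details matter:

- **Ridge stabilization.** Real LD matrices are rank-deficient. A ridge
  δ (default 1e-4) is added to the diagonal of Σ_X before any
  factorization, identically in every code path. This guarantees
  positive definiteness without visibly distorting correlations; it is
  the only modification ever applied to the input LD.
- **Low-rank path.** With support S = {i : cᵢ > 0}, Σ is a rank-|S|
  update of the stabilized A = Σ_X + δI. Because A⁻¹A[:,S] = I[:,S],
  the Woodbury identity collapses to k×k solves:
  log det Σ = log det A + Σᵢ log sᵢ + log det M and
  zᵀΣ⁻¹z = zᵀA⁻¹z − z_Sᵀ M⁻¹ z_S, with s = nσ²c_S and
  M = diag(1/s) + A[S,S]. After the one-time Cholesky of A, each
  likelihood or gradient evaluation costs O(k³ + k²), not O(m³). The
  gradient needed for training has the closed form
  ∂ log N/∂cᵢ = −½ nσ² (aᵢᵀΣ⁻¹aᵢ − (aᵢᵀΣ⁻¹z)²), aᵢ = A[:,i],
  again reducible to k×k solves on the support. Below m = 128 the dense
  Cholesky path is used instead ("auto" dispatch): at small m it is as
  cheap and numerically tightest.

σ² defaults to 0.005 so that n·σ² = 25 at the reference n = 5000 — the
conventional standardized-effect scale in summary-statistic
fine-mapping. All priors are user-configurable.

## Variational approximation

The posterior over causal configurations is approximated by an
independent binary concrete distribution q(c; p, λ). The temperature λ
is annealed geometrically from 0.5 to 0.01 over the T iterations
(per-iteration schedule); at the final temperature the distribution is
effectively Bernoulli and the closed-form Bernoulli KL to the prior
(inclusion probability p₀ = 1/m, temperature λ₀ = 0.01) is an accurate
stand-in for the intractable concrete–concrete KL. The exact concrete
KL has no closed form and is not implemented.

The probability map p = F(z; φ) is produced by a fully connected
network z → 256 → 256 → m (elementwise ReLU between layers, sigmoid
output clamped to [1e-6, 1−1e-6]), trained per locus from random
initialization. Training amortized across loci is deliberately out of
scope — each locus gets its own φ, which keeps the method free of any
training corpus. The network and its backpropagation are implemented
directly in NumPy: the gradient of the loss with respect to p has a
closed form (the likelihood gradient above, chained through the
reparameterized sampler via ∂cᵢ/∂pᵢ = cᵢ(1−cᵢ)/(λ pᵢ(1−pᵢ)), plus the
Bernoulli KL gradient), so a full autograd framework buys nothing.
Parameters are updated with Adam (step 1e-3); defaults are T = 2000
iterations with L = 10 Monte Carlo samples per iteration.

Per sample, entries with cᵢ ≤ 0.01 are zeroed and, if more than 50
entries survive, only the 50 largest are kept (ties broken by lowest
index). Pruning acts as a hard gate: pruned coordinates pass no
gradient. Each pruned sample is thresholded at γ = 0.1 into a binary
configuration and added to the harvested set; pruning before
binarization is what guarantees every harvested configuration has
support ≤ 50.

Output clamping, the open-interval guard on the uniform draws, and the
strict (>) binarization inequality are the only tie/boundary rules; all
are deterministic, and every stochastic operation accepts a seed or
explicit uniform draws, so identical seeds reproduce the harvested set,
loss trace, and outputs bit for bit.

## Posterior summaries

The harvested configurations stand in for the full 2^m configuration
space. Each is reweighted exactly, weight(b) ∝ N(z; 0, Σ(b)) ·
p₀^|b|(1−p₀)^(m−|b|), normalized with a log-sum-exp guard; harvest
multiplicities are diagnostics only. PIPs are sums of configuration
weights.

**The null configuration is always included in the harvested set.**
Sampling almost never produces the all-zero configuration when p is
moderate (probability (1−p)^m per draw), and without it the renormalized
posterior is implicitly conditioned on "at least the smallest sampled
support being causal" — under weak data this forced spurious PIPs near 1.
Anchoring the set with the no-causal configuration restores the correct
behavior (null loci get PIP ≈ 0 everywhere) and is inconsequential under
real signal, which outweighs the null configuration exponentially.

Credible sets are built in two steps over the configuration posterior.
Step 1 greedily selects "key" variants: the next key maximizes the
conditional probability of being causal given the keys already chosen;
selection stops when that probability drops below 0.5 or when max_sets
(default 10) is reached. Step 2 builds one set per key by ranking
variants on conditional inclusion probability given the *other* keys and
accumulating until the cumulative probability reaches the coverage
target (default 0.95); ties break by larger |z|, then lower index. If
the coverage cannot be reached, the set holds the full remaining support
and is flagged incomplete. The two-step procedure is an interpretation
of a conditional stepwise construction whose exact recursion is not
fully specified in the literature this follows; no LD-purity filter is
applied to the resulting sets. A structural consequence of the stopping
rule: when every configuration has support ≤ s, at most s sets are
produced.

## Simulation design

Genotypes come from a latent-Gaussian haplotype model: within each block
of `ld_block_size` variants the latent variables follow an AR(1) with
parameter `ld_rho` (independent across blocks and haplotypes); each
variant's minor-allele frequency is uniform on [maf_min, 0.5] with
maf_min = 0.02, and alleles are assigned by *rank* thresholding, so the
minor-allele count is met exactly and the MAF floor is a deterministic
guarantee. Genotype = sum of two haplotypes.

The trait is a mixed model: d causal fixed effects β ~ N(0, I_d), a
non-causal random effect with covariance X_NC X_NCᵀ/(m−d), and Gaussian
noise. All three components are rescaled by their empirical standard
deviations so the causal, non-causal, and noise parts explain exactly
share·ω², (1−share)·ω², and 1−ω² of the trait variance; total variance
is then 1 up to the (small) empirical cross-covariances of the
components. Summary statistics mimic a real pipeline: per-variant
simple OLS on the *raw* dosages, z = β̂/se(β̂) clipped at |z| = 200, LD
as XᵀX/n on standardized genotypes.

What the generator does **not** emulate: coalescent-realistic LD decay
and haplotype sharing, realistic allele-frequency spectra, imputation
error, or relatedness. Passing tests therefore demonstrate correctness
of the method under block-AR LD and the stated variance partition, not
performance on any particular real locus.

## Problem sizes and observed behavior

The bundled recovery study uses n = 5000 individuals and m = 100
variants per locus with 20 replicates — large enough that a single
causal variant explaining 0.54 of the trait variance yields |z| ≈ 50–80,
small enough that a full study runs in minutes on one CPU. At this scale
the top-PIP variant is the planted causal one in ≥ 19/20 replicates and
the union of credible sets captures it in all replicates.

One behavior deserves emphasis. Holding the non-causal variance share
fixed while shrinking m concentrates the polygenic background: at
m = 100 with (1−share)·ω² = 0.06, each non-causal variant carries an
expected z-inflation of n·b² ≈ 3 (χ²-distributed), so every replicate
contains several non-causal variants with |z| ≈ 4–6. Under the model's
own prior these variants have exact posterior inclusion probabilities of
0.85–0.96 (closed form at zero LD:
ξ(½z²·nσ²/(1+nσ²) − ½log(1+nσ²) + logit(p₀))), and any faithful
posterior approximation emits credible sets keyed on them. Coverage
measured against the fixed-effect truth therefore drops to ≈ 0.14 at
this scale — a property of the evaluation convention under a
concentrated polygenic background, not an inference defect; at m = 1000
the same share spreads ten times thinner and the effect largely
disappears. The test suite states the coverage expectation at the
scaled-down conditions and it fails there for exactly this reason; the
accompanying top-hit, power, AUPRC, and null-behavior checks all pass.

## Known limitations

- Posterior effect sizes are not estimated; c models only the variance
  pattern of the effects.
- The factorized proposal cannot represent strong negative dependence
  between variants in a tight LD block; the configuration reweighting
  partially compensates, since weights are exact for every harvested
  configuration.
- The reduced configuration set is biased toward configurations near the
  fitted probability map; PIPs of borderline variants can be
  overestimated when their exclusion configurations are rarely sampled.
- Per-locus network training adds optimizer noise: different seeds can
  flip PIPs of variants in near-perfect LD.
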