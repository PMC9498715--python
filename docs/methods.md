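# Methods

## Model

All fits are Bayesian linear mixed models

y = Xβ + Σ_b W_b γ_b + Σ_k u_k + e

* **Fixed effects** β: intercept plus the fixed-covariate columns of the
  phenotype table. Continuous covariates enter as-is; categorical ones are
  dummy-coded with the first level dropped. Flat prior.
* **Class-effect blocks** γ_b (diet, slaughter day, pen …): full dummy coding
  (no level dropped), each column under a BayesB mixture prior — zero with
  probability π, otherwise Gaussian with its own scaled-inverse-χ²(df, S)
  variance. Fitting categorical terms with BayesB is unusual but is the
  convention this pipeline follows; `class_effects_as="gaussian"` switches the
  blocks to a plain Gaussian (ridge) prior, which is π = 0.
* **Kernel (RKHS) random effects** u_k ~ N(0, K_k σ²_k) for any subset of
  {GRM, MRM, Hadamard, CORE}. Kernels are normalised to mean diagonal 1
  before fitting so the σ²_k are on a common scale and can be read as
  variance fractions of an (approximately) unit-variance trait.
* **Residual** e ~ N(0, I σ²_e), scaled-inverse-χ² prior.

Five model labels map onto kernel subsets: `genomic` {G}, `microbial` {M},
`direct` {G, M}, `core` {G, M, K_core}, `hadamard` {G, M, G∘M}.

## Kernels

* **GRM** (VanRaden): G = (Z − 2Q)(Z − 2Q)' / Σ_m 2p_m(1 − p_m), allele
  frequencies computed from non-missing dosages; missing dosages mean-imputed
  to 2p_m (the standard VanRaden-compatible choice). Monomorphic SNPs are an
  error — filter at MAF ≥ 0.01 first (the conventional threshold, and the
  package default).
* **MRM**: counts → per-sample relative abundances; zeros replaced by half
  the smallest nonzero relative abundance in the whole table; natural log;
  each OTU column centred and scaled to unit variance (sd with n−1, matching
  R's `scale()`); M = RR'/q with q the number of OTU columns kept.
  Zero-variance columns are dropped with a warning. Per-OTU (not per-sample)
  standardisation is a deliberate choice; the alternative reading exists but
  per-OTU scaling is standard MRM practice and gives mean diagonal ≈ 1.
* **Hadamard**: K = G ∘ M entry-wise. PSD whenever both inputs are
  (Schur product theorem), checked in the test suite.
* **CORE**: K = ½(L_G L_M' + L_M L_G') with L the lower Cholesky factors.
  This symmetrised cross-product is the covariance structure used when the
  genomic and microbial random effects are allowed to covary; the ½ makes
  K(G, G) = G exactly. If a factorisation fails, a ridge εI is added with ε
  growing from 1e-10 by ×10 up to 1e-6, then the construction fails loudly.
  The CORE kernel may be indefinite; its smallest eigenvalue is logged and
  negative eigenvalues are truncated (with a logged count) when the kernel is
  used as an RKHS covariance.

## Gibbs sampler

One sweep updates, in order: fixed effects (single-site, flat prior), each
BayesB column (variance, then inclusion + effect from the marginal-likelihood
odds), each kernel term, then the residual variance. Samples with missing
phenotypes contribute nothing to the likelihood.

Kernel terms are sampled in the eigenbasis of the kernel **restricted to the
observed samples**: with K_oo = U D U′ (eigenvalues below 1e-8 × max
truncated) and u_obs = U D^{1/2} t, the coefficients t_j ~ N(0, σ²_k) have a
diagonal full conditional because U is orthonormal, so the whole block is one
matrix-vector product per sweep. Masked samples are predicted at each kept
iteration by kernel regression, u_miss = K_mo K_oo⁺ u_obs =
(K_mo U D^{-1/2}) t. This is algebraically the same model as carrying the
masked rows through the sampler with zero likelihood weight (the conditional
mean of u_miss given u_obs does not depend on σ²), and its posterior mean is
identical; it is used because it vectorises.

σ²_k | t ~ scaled-inv-χ²(df + m, (df·S + Σt²)/(df + m)); the residual update
is analogous with the observed-sample count. `fixed_variances` pins any
subset of variances (used for the BLUP-equivalence check). The chain is
deterministic given the seed.

**Priors and defaults.** 12,000 iterations, 2,000 burn-in, thinning 5
(conventional Bayesian-alphabet scale; the tests and acceptance script use
shorter chains sized to their problems — convergence at those sizes was
checked by extending chains ×10 with no change in posterior means).
π = 0.5, all variance df = 5. Scales follow the expected-proportion-of-
variance rule: the prior mean of each random term's variance equals
`r2_total · var(y)` split equally over the random terms (r2_total = 0.5), and
the residual prior mean is `(1 − r2_total) · var(y)`; for scaled-inv-χ²(ν, S)
the mean is νS/(ν−2), so S = target·(ν−2)/ν. BayesB scales divide the block
target by (1 − π) Σ_j var(w_j). An equal-split "balanced" prior (every term
including the residual getting the same prior mean) was evaluated during
development and rejected: on weakly identified directions it over-allocates
variance to near-identity interaction kernels.

## Cross-validation and comparison

`make_folds` draws balanced random partitions (sizes differ by ≤ 1), one per
repeat, deterministic given the seed; the default protocol is 10-fold CV
repeated 10 times. Each (repeat, fold) masks the fold's phenotypes, refits
the model from scratch (the masked samples stay in the kernels), predicts the
fold, and scores r² = squared Pearson correlation against the raw observed
phenotypes (not pre-adjusted residuals — the simplest reading of the
protocol). Folds with fewer than 3 validation samples are rejected up front
(r² would be degenerate); note the fold *constructor* allows singleton folds,
so leave-one-out partitions can still be built for other purposes. Accuracy
is reported as mean ± SD of the per-repeat means (SE available via a flag).
Per-fit MCMC seeds are derived from (base seed, repeat, fold) so the whole
procedure is reproducible bit-for-bit.

`compare_models` runs one-way ANOVA on the per-repeat r² values (sums of
squares computed directly; F = 0, p = 1 when the between-group sum of squares
is exactly zero) and Tukey HSD pairwise comparisons (statsmodels) at α = 0.05.
Tukey is the standard companion to one-way ANOVA; the repeats share folds
across models, which makes the comparison conservative for detecting
between-model differences.

## Synthetic data

The generator emulates a livestock holo-omics study:

* **Herd/family structure.** Samples are assigned to `n_groups` (default 25)
  balanced groups. Group allele frequencies follow a Balding-Nichols model
  around the global frequencies (Var[p_g] = Fst·p(1−p), Fst = 0.1), and each
  group has its own microbiome base composition drawn around the global base
  (Dirichlet, concentration `otu_group_concentration` = 3). This matters:
  with fully unstructured samples the Hadamard kernel G∘M collapses towards
  the identity (its off-diagonals are products of two near-zero entries) and
  the interaction variance becomes unidentifiable from residual noise — for
  a converged sampler and for maximum likelihood alike. Group structure is
  what real herds have and what makes the interaction term estimable.
* **Genotypes**: per-SNP global frequency uniform on `maf_range`
  (default 0.05–0.5), dosages Binomial(2, p_group); SNPs whose realised MAF
  falls below 0.01 are redrawn. Optional missingness exercises imputation.
* **OTU counts**: Dirichlet-multinomial per sample around the group base
  (per-sample concentration 0.3, depth 10,000 reads) — compositional,
  overdispersed, sparse enough that the 20% prevalence filter has bite.
* **Phenotype**: y = fixed + g + m + gm + e with g ~ N(0, G·var_g),
  m ~ N(0, M·var_m), gm ~ N(0, (G∘M)·var_gm) drawn from the kernels built
  from the simulated data themselves (normalised to mean diagonal 1), and
  iid noise. Fractions must sum to 1. The interaction is generated under the
  Hadamard kernel — the best-performing framework — so that "the interaction
  model should beat the additive model" is a testable property. Farm (fixed)
  and diet (class) level effects are drawn centred to zero mean, so a single
  level is exactly "no effect".
* **g–m correlation** (default 0): `gm_correlation` mixes a shared latent
  vector drawn on the blended kernel (G+M)/2 into both effects, giving
  corr(g_i, m_i) ≈ ρ. This is a stand-in to exercise CORE modelling, not a
  generative claim; mixing latent *coefficients* through the factors of
  unrelated kernels would produce no per-sample correlation.

What the generator does **not** emulate: linkage disequilibrium, explicit
pedigrees, read-level 16S sequencing, longitudinal microbiome drift, or any
real genotype–microbiome dependence beyond the optional shared latent. Tests
passing on this generator show the machinery is correct and calibrated under
its assumptions; they do not certify accuracy levels on real animal data.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so each check
is informative for its property: kernel oracles at n ≤ 8 (exhaustive
brute-force comparison), BLUP equivalence at n = 100, variance-fraction
recovery at n = 400 with 1,000 SNPs / 200 OTUs over 5–10 seeds, CV ranking at
n = 250 with single-repeat 10-fold CV over 10 seeds, and null calibration at
n = 400 (fold size 40: the null expectation of r² on an m-sample fold is
≈ 1/(m−1), so fold size must be large enough for the no-signal level to be
meaningfully small).

## Numerical notes

* Kernels are symmetrised (½(K + K′)) after construction to remove rounding
  asymmetry; constructors validate symmetry to 1e-10 and finiteness.
* Eigenvalues below 1e-8 × max are truncated in the RKHS basis.
* Dosage/abundance validation is strict (cells outside {0,1,2,NA} or negative
  abundances are errors naming the offending cell; mixed count/relative OTU
  tables are rejected rather than guessed).
* All CSV outputs are written with fixed 12-significant-digit formatting so
  that re-running a config reproduces files byte-for-byte.

## Known limitations

* Variance components attached to interaction kernels are reported as
  variances (σ²), not signed covariances, even where the quantity is
  conceptually a covariance between effects; a scaled-inverse-χ² prior cannot
  go negative. A signed-covariance parameterisation would need a different
  sampler.
* BayesB hyperparameters (π, df, scale) are fixed, not estimated.
* Folds are unstratified; farm/pen stratification is not implemented.
* No REML/frequentist path, multi-trait models, or convergence diagnostics
  beyond determinism and the test suite's calibration checks.
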