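# Methods

## Model

`regpoly` estimates the regional polygenicity p_r — the proportion of SNPs
in a genomic region with a nonzero effect on a quantitative trait — from
GWAS summary statistics. For a region with M_r SNPs the generative model is
a spike-and-slab regression on standardized genotypes and phenotype:

- causal statuses c_m ~ Bernoulli(p_r), m = 1..M_r;
- slab effects gamma_m ~ N(0, sigma_g^2) with sigma_g^2 = h_r^2/(M_r p_r),
  so the region's expected heritability equals h_r^2 regardless of p_r;
- true effects beta_m = gamma_m c_m;
- GWAS marginal effects beta_hat | beta ~ N(V beta, V sigma_e^2), where V is
  the regional LD (SNP correlation) matrix and sigma_e^2 = (1 - h_r^2)/N;
- prior p_r ~ Beta(alpha, alpha) with alpha = 0.2 by default (heavier mass
  near 0 and 1 than the flat prior).

Inputs per region: marginal effects on the standardized scale
(beta_hat = z/sqrt(N)), the LD matrix (in-sample LD strongly preferred — see
the LD-mismatch experiment below), an external regional-heritability
estimate h_r^2, and the GWAS sample size N. The model treats h_r^2 as known;
regions are assumed independent (appropriate for LD-block or multi-megabase
windows).

## Whitening and the LD factorization

Inference works with whitened effects beta_tilde = V^{-1/2} beta_hat, whose
conditional distribution is N(V^{1/2} beta, sigma_e^2 I): residual noise is
independent across coordinates. V is eigendecomposed once per region;
components with eigenvalue below 1e-8 × the largest are truncated, and the
factor A = Lambda_+^{1/2} U_+^T (rank × M_r) plays the role of V^{1/2}. On
the retained subspace the model beta_tilde | beta ~ N(A beta, sigma_e^2
I_rank) is exact, which is how rank-deficient LD (duplicate SNPs, finite
panels) is handled. The transform is computed once and cached with the
region, together with b_m = beta_tilde^T A_{.m} for every SNP.

Because A_{.l}^T A_{.m} = V_lm (exactly at full rank; A^T A under
truncation), the sampler never needs A itself during iteration — only b and
entries of the Gram matrix.

## Inference

A Gibbs sampler with one Metropolis-Hastings sub-step:

1. **Block (gamma_m, c_m) update per SNP.** The spike is collapsed: the
   inclusion probability integrates gamma_m out analytically,
   d_m = logistic( log(p/(1-p)) + 1/2 log(sigma_m^2/sigma_g^2)
   + mu_m^2/(2 sigma_m^2) ), with
   1/sigma_m^2 = 1/sigma_g^2 + G_mm/sigma_e^2 and
   mu_m = (sigma_m^2/sigma_e^2) (b_m - sum_{l != m, c_l = 1} G_ml gamma_l).
   If c_m = 1 is drawn, gamma_m ~ N(mu_m, sigma_m^2); otherwise gamma_m = 0.
   Non-causal gammas are not part of the state (no prior-resampling step).
   The logistic/log-space form is essential: exp(mu^2/2 sigma^2) overflows
   routinely at biobank sample sizes.
2. **MH update of p.** The full conditional of p involves both the causal
   counts and the causal gammas (p parametrizes the slab variance). A Beta
   proposal Beta(alpha + C p, alpha + C(1-p)) with C = 10 is used, accepted
   with the standard Metropolis-Hastings ratio including the Hastings
   correction for the proposal's asymmetry.

One iteration = one sweep over all SNPs (fixed ascending order by default; a
per-iteration random permutation is available) followed by one MH update.
Defaults: 1000 iterations, 250 burn-in. Initialization: c_m = 1 iff
|z_m| >= 3.5 (absolute value — initializing only positive-effect SNPs would
be incoherent), p_0 = mean(c) clamped to [1/M_r, 1 - 1/M_r], gamma from the
slab prior at p_0.

**Degenerate p.** sigma_g^2 = h^2/(M p) diverges as p -> 0, so p is clamped
to [1/(10 M_r), 1 - 1/(10 M_r)] wherever sigma_g^2 or proposal parameters
are evaluated. The clamp is part of the implemented model: the enumeration
oracle applies it identically, so chain and oracle target the same density.

**Sparse arithmetic.** The residual inner product is accumulated over causal
SNPs only, so one iteration costs O(K_r M_r) (K_r = current causal count)
instead of O(M_r^2). The `naive` engine performs the same arithmetic while
rediscovering the causal set by scanning all M_r statuses per SNP update
(O(M_r^2)/iteration); both accumulate in ascending SNP order, so the two
engines produce bit-identical chains under a shared seed — the speedup is
verified as an operation-count property, not a wall-clock number. The inner
loop is compiled with numba; the first call in a fresh environment pays a
one-time compilation cost.

**Exact oracle.** For M_r <= 12 the posterior is computed exactly by
enumerating all 2^M causal configurations with gamma integrated out
(Woodbury identities on the configuration's Gram block) and integrating p by
midpoint quadrature on the interior plus analytic incomplete-Beta tails
(where the clamp makes the likelihood constant). The Gibbs sampler is tested
against this oracle, and the oracle itself against an independent dense
multivariate-normal quadrature.

**Inclusion Bayes-factor variants.** The exact marginalization gives the
sqrt(sigma_m^2/sigma_g^2) prefactor above and is the default
(`inclusion_bf="exact"`), confirmed by the enumeration oracle. A
`"conservative"` variant replaces the square root by the plain ratio,
suppressing weakly supported inclusions; it is strongly downward biased at
every signal strength we measured and exists as a documented option only.

## Posterior summaries and reporting

Per region: posterior mean, SD and equal-tailed 95% credible interval of
p_r from retained draws; causal-count summaries are M_r × the p summaries
(an exact per-draw identity). A region is called **nonzero** when
p_mean − 2 p_sd > 0. Genome-wide polygenicity is the SNP-count-weighted mean
of regional posterior means (equivalently summed expected causal counts over
total SNPs); intervals come from 10^4 independent resamples of each region's
chain, relying on cross-region posterior independence. "At least k causal
SNPs" uses mc_mean − 2 mc_sd >= k for k > 1 (mirroring the nonzero rule; a
posterior-probability rule is available as an option). The
heritability-versus-counts analysis is ordinary least squares (statsmodels)
of h_r^2 on M_r, on Mc_r, and on both, with outliers flagged at
|externally studentized residual| > 3.

## Synthetic data

Two generation routes with exactly the model's structure:

- **summary level**: c ~ Bernoulli(p_r); gamma at variance h_r^2/(M_r p_r)
  (or an explicit Gaussian mixture, causal SNPs spread equally across
  components in expectation); beta_hat = V beta + sigma_e A^T z.
- **genotype level**: standardized Gaussian genotypes with population
  correlation V, phenotypes y = X beta + eps with eps ~ N(0, (1-h_GW^2) I),
  OLS effects beta_hat = X^T y/N. With V the in-sample X^T X/N the two
  routes are distributionally identical (tested).

Genotypes are Gaussian copies rather than binomial allele draws: the model
consumes only standardized genotypes and their correlation, and the Gaussian
construction controls V exactly. Not emulated: allele-frequency spectra,
missingness, imputation dosages, population structure, non-random
ascertainment. Passing tests therefore demonstrate correctness of the
sampler and of the model's own claims, not robustness to real-data artifacts.

Synthetic LD: identity, ar1(rho) (V_lm = rho^|l-m|), constant-correlation
blocks, or the sample LD of simulated genotypes. The replication studies use
ar1(0.9) at M_r = 1000 in place of biobank in-sample LD.

## Study conditions for the replication experiments

- Regional heritability scaled from a genome-wide value:
  h_r^2 = h_GW^2 M_r/M_total with M_total = 470,000 (a genome of 470 6-Mb
  regions averaging 1000 array SNPs), so h_GW^2 = 0.5 gives
  h_r^2 ≈ 1.06e-3 at M_r = 1000. The per-causal-SNP signal-to-noise ratio
  sigma_g^2/sigma_e^2 — the quantity that controls estimator behavior —
  is then ~106, 53, 10.6 and 5.3 across the p_r grid
  {0.005, 0.01, 0.05, 0.10} at N = 500K.
- The multi-region genotype-level study uses 6 regions × 1000 SNPs with
  ar1(0.9) LD per region (block-diagonal across regions), genotypes drawn
  once and held fixed across replicates, genome-wide p = 0.01, and
  (h_GW^2 = 0.8, N = 52,886) chosen so the per-causal-SNP signal-to-noise
  matches a chromosome-22-scale study at N = 337K, h^2 = 0.5
  (sigma_g^2/sigma_e^2 ≈ 3526). The regional-heritability input is the
  quadratic-form plug-in (N ||beta_tilde||^2 − q)/(N − q), the slot an
  external heritability estimator would fill. This experiment runs 3000
  iterations with a 1500-iteration burn-in: at this signal strength causal
  z-scores are ~60, so the |z| >= 3.5 initialization marks entire LD
  neighborhoods causal (~20x the true count); most chains decay within ~50
  iterations but occasional replicates are metastable for hundreds, and the
  default 250-iteration burn-in retains a measurable transient (+4–8
  points of apparent bias). The extended burn-in was chosen from trace
  diagnostics of K_r.
- The LD-mismatch experiment simulates with ar1(0.9), then infers with (i)
  the same matrix, (ii) LD estimated from an independent 20K-genotype panel
  drawn from the same population LD, and (iii) an identity matrix
  (structural mismatch).

## Monte-Carlo precision of the bias experiments

Per-replicate posterior means track the realized causal count K_r, whose
relative SD is 31–45% of p_r at p_r <= 0.01 — far above the few-percent bias
bands of interest at practical replicate counts. All bias estimates
therefore use a regression-adjusted control variate on K_r/M_r (known
expectation p_r): unbiased for the same estimand, with variance reduced by
the squared estimate/count correlation. Replicate counts (250–600 per
setting in the acceptance script; >= 40 in tests) were budgeted so the
residual MC standard error is small relative to the quantities measured.
Paired common-random-number designs are used when two inference conditions
are compared on the same data.

## Estimator behavior across signal regimes (what the experiments show)

The frequentist bias of the posterior mean at fixed truth is governed almost
entirely by the per-causal-SNP signal-to-noise ratio s = sigma_g^2/sigma_e^2
and the causal count K_r, not by the LD structure (identity and ar1(0.9)
give similar curves):

- s >~ 25 and K_r >~ 10: approximately unbiased (a few percent, upward);
- s in roughly 2–20: **upward** bias of +15–45% — p_r is only weakly
  identified there (p_r · sigma_g^2 is pinned by h_r^2, so only the shape of
  the effect-size distribution distinguishes many small effects from few
  large ones) and the right-skewed posterior mean overshoots on average;
- s <~ 1: strong downward bias (−20% at s ≈ 1, −55% at s ≈ 0.5, worse
  below), as causal effects become indistinguishable from noise;
- small K_r inflates the upward skew at any s (e.g. ~+20% at K_r = 5).

These are properties of the exact posterior — verified with the MCMC-free
enumeration oracle — not sampler artifacts. Consequences worth knowing
before applying the method: estimates in regions where the implied s is
below ~25 should be treated as order-of-magnitude statements, and the
posterior mean is prior-sensitive in the weakly identified regime (the
replicate-averaged estimate is stable across alpha in {0.2, 1, 2}, but
individual weak-signal regions can move by more than one posterior SD).

## Numerical choices

- All densities in log space; logistic form for inclusion probabilities.
- Eigenvalue truncation threshold 1e-8 relative to the largest eigenvalue.
- One seeded generator per run; in multi-region runs each region's seed is
  derived from the global seed and the region index, so regions are
  independent but individually reproducible.
- Posterior intervals are empirical 2.5/97.5 percentiles of retained draws.
- The k = 1 threshold rule is the nonzero call itself, keeping the two
  reporting rules consistent.
- Negative external heritability estimates are floored at 1e-6 with a
  warning (unbiased quadratic-form estimators can go negative; the model
  requires h_r^2 > 0).

## Known limitations

- h_r^2 is plugged in, not jointly estimated; its error propagates
  unmodeled.
- No annotation-aware priors, no multi-ancestry support, no imputed-dosage
  handling, no strand/allele harmonization (LD and summary statistics must
  come from the same genotype source; only SNP-id order is checked).
- Genome-wide intervals assume independent regions; long-range LD violates
  this.
- The weak-identification biases described above are intrinsic to the model
  at low per-SNP signal; no sampler improvement can remove them.
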