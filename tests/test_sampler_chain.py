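"""Full-chain correctness: enumeration oracle, MH target, engine equivalence."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from regpoly.ld import factorize, whiten
from regpoly.sampler import (
    SamplerConfig,
    enumerate_posterior,
    init_state,
    log_conditional_p,
    mc_standard_error,
    mh_update_p,
    model_constants,
    run_gibbs,
    update_snp,
)
from regpoly.simulate import (
    SimulationSpec,
    draw_architecture,
    make_ld,
    simulate_sumstats,
)


class TestEnumerationOracle:
    def test_uninformative_single_snp_pip_near_prior_mean(self):
        """M=1, beta_tilde = 0, huge sigma_e2: P(c=1) equals the prior mean
        of p (0.5 for the symmetric Beta prior)."""
        fac = factorize(make_ld("identity", 1))
        region = whiten(np.zeros(1), fac, n=10, h2_r=1e-6)
        post = enumerate_posterior(region, alpha=0.2)
        assert post.pip[0] == pytest.approx(0.5, abs=0.02)
        assert post.p_mean == pytest.approx(0.5, abs=0.02)

    def test_exchangeable_snps_have_equal_pips(self):
        fac = factorize(make_ld("block", 2, rho=0.4, block_sizes=(2,)))
        beta_hat = np.array([0.05, 0.05])  # symmetric data
        region = whiten(beta_hat, fac, n=500, h2_r=0.1)
        post = enumerate_posterior(region)
        assert post.pip[0] == pytest.approx(post.pip[1], abs=1e-9)

    def test_agrees_with_independent_dense_quadrature(self, ar1_region_factory):
        """Woodbury + incomplete-Beta tails vs dense multivariate-normal
        likelihoods integrated with adaptive quadrature."""
        from scipy.integrate import quad

        region, _, _ = ar1_region_factory(m=3, rho=0.5, p_r=0.4, h2_r=0.3, n=200, seed=1)
        m = region.m_r
        alpha = 0.2
        p_lo = 1.0 / (10 * m)
        p_hi = 1.0 - p_lo
        a = region.ld.sqrt_rows
        bt = region.beta_tilde
        se2 = region.sigma_e2

        def loglik(code, sg2):
            idx = [i for i in range(m) if (code >> i) & 1]
            cov = se2 * np.eye(region.ld.rank)
            if idx:
                ac = a[:, idx]
                cov = cov + sg2 * (ac @ ac.T)
            return multivariate_normal(np.zeros(region.ld.rank), cov).logpdf(bt)

        z = 0.0
        num = 0.0
        pip_num = np.zeros(m)
        for code in range(2**m):
            k = bin(code).count("1")

            def integrand(p, code=code, k=k):
                pc = min(max(p, p_lo), p_hi)
                return math.exp(
                    loglik(code, region.h2_r / (m * pc))
                    + (k + alpha - 1) * math.log(p)
                    + (m - k + alpha - 1) * math.log1p(-p)
                )

            mass, _ = quad(integrand, 0, 1, points=[p_lo, p_hi], limit=200)
            mean_, _ = quad(lambda p: p * integrand(p), 0, 1, points=[p_lo, p_hi], limit=200)
            z += mass
            num += mean_
            for i in range(m):
                if (code >> i) & 1:
                    pip_num[i] += mass

        post = enumerate_posterior(region, alpha=alpha)
        assert post.p_mean == pytest.approx(num / z, rel=1e-5)
        assert np.allclose(post.pip, pip_num / z, atol=1e-5)

    def test_large_region_rejected(self):
        fac = factorize(make_ld("identity", 15))
        region = whiten(np.zeros(15), fac, n=100, h2_r=0.1)
        with pytest.raises(ValueError, match="enumeration"):
            enumerate_posterior(region)


class TestGibbsMatchesOracle:
    def test_posterior_summaries_within_monte_carlo_error(self, ar1_region_factory):
        """Across 10 seeds/datasets on small regions, the Gibbs posterior
        mean/SD of p and all per-SNP inclusion probabilities agree with the
        enumeration + quadrature oracle within 3 Monte-Carlo SEs."""
        n_bad = 0
        for seed in range(10):
            region, _, _ = ar1_region_factory(
                m=5, rho=0.6, p_r=0.3, h2_r=0.05, n=1500, seed=seed
            )
            oracle = enumerate_posterior(region)
            draws = run_gibbs(
                region, SamplerConfig(n_iter=60000, burn_in=5000, seed=1000 + seed)
            )
            se_p = max(mc_standard_error(draws.p_samples, n_batches=40), 1e-4)
            assert abs(draws.p_mean - oracle.p_mean) < 3 * se_p, f"seed {seed}"
            assert abs(draws.p_sd - oracle.p_sd) < 0.1 * oracle.p_sd + 3 * se_p
            for m in range(region.m_r):
                # binomial-style bound with an autocorrelation inflation factor
                se_bin = math.sqrt(
                    max(draws.pip[m] * (1 - draws.pip[m]), 1e-4)
                    / len(draws.p_samples)
                    * 20
                )
                if abs(draws.pip[m] - oracle.pip[m]) > max(3 * se_bin, 0.02):
                    n_bad += 1
        assert n_bad == 0

    def test_fixed_p_inclusion_matches_conditional_enumeration(self, ar1_region_factory, rng):
        """Holding p fixed, a long chain of block (gamma, c) updates matches
        the exact conditional P(c | p, data) from configuration enumeration."""
        region, _, _ = ar1_region_factory(m=3, rho=0.5, p_r=0.4, h2_r=0.2, n=400, seed=17)
        p_fixed = 0.35
        consts = model_constants(region.h2_r, region.n, region.m_r, p_fixed)
        gram = region.ld.gram()
        b = region.b
        ss = region.beta_tilde_ss
        rank = region.ld.rank

        # exact conditional via gamma-integrated likelihood per configuration
        weights = []
        for code in range(8):
            idx = [i for i in range(3) if (code >> i) & 1]
            k = len(idx)
            if k:
                g_cc = gram[np.ix_(idx, idx)]
                mat = (consts.sigma_e2 / consts.sigma_g2) * np.eye(k) + g_cc
                sign, logdet = np.linalg.slogdet(mat)
                quad_term = ss - b[idx] @ np.linalg.solve(mat, b[idx])
                ll = -0.5 * (
                    logdet
                    - k * math.log(consts.sigma_e2 / consts.sigma_g2)
                    + quad_term / consts.sigma_e2
                )
            else:
                ll = -0.5 * ss / consts.sigma_e2
            weights.append(math.exp(ll) * p_fixed**k * (1 - p_fixed) ** (3 - k))
        weights = np.array(weights)
        weights /= weights.sum()
        pip_exact = np.array(
            [sum(w for code, w in enumerate(weights) if (code >> i) & 1) for i in range(3)]
        )

        state = init_state(np.zeros(3), SamplerConfig(seed=2), region, rng=rng)
        state.p = p_fixed
        n_sweeps = 40000
        counts = np.zeros(3)
        for _ in range(n_sweeps):
            for m in range(3):
                update_snp(m, state, region, rng, consts)
            counts += state.c
        pip_hat = counts / n_sweeps
        se = np.sqrt(pip_exact * (1 - pip_exact) / n_sweeps) * math.sqrt(10)
        assert np.all(np.abs(pip_hat - pip_exact) < np.maximum(3 * se, 0.01))

    def test_mh_chain_matches_grid_normalized_conditional(self, ar1_region_factory, rng):
        """With (c, gamma) frozen, the MH p-chain's empirical distribution
        matches the grid-normalized conditional density (KS below the 1%
        critical value on thinned draws)."""
        region, _, _ = ar1_region_factory(m=10, p_r=0.3, h2_r=0.1, n=800, seed=23)
        cfg = SamplerConfig()
        # freeze a state with 3 causal SNPs so the conditional density of p
        # vanishes at both endpoints and the grid CDF is well conditioned
        z = np.array([4.0, 4.0, 4.0, 0, 0, 0, 0, 0, 0, 0])
        state = init_state(z, cfg, region, rng=rng)
        k = state.k
        assert k == 3
        gamma_causal = state.gamma[state.c == 1]

        n_sweeps = 200_000
        thin = 20
        draws = np.empty(n_sweeps // thin)
        for i in range(n_sweeps):
            mh_update_p(state, region, cfg, rng)
            if i % thin == thin - 1:
                draws[i // thin] = state.p

        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        logd = np.array(
            [log_conditional_p(p, k, 10, gamma_causal, region.h2_r, cfg.alpha) for p in grid]
        )
        dens = np.exp(logd - logd.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        u = np.interp(draws, grid, cdf)
        ks = stats.kstest(u, "uniform").statistic
        crit_1pct = 1.63 / math.sqrt(len(draws))
        assert ks < crit_1pct


class TestEngines:
    def test_sparse_and_naive_chains_bit_identical(self, ar1_region_factory):
        region, _, _ = ar1_region_factory(m=40, p_r=0.2, h2_r=0.2, n=2000, seed=31)
        base = dict(n_iter=400, burn_in=50, seed=9)
        d_sparse = run_gibbs(region, SamplerConfig(engine="sparse", **base))
        d_naive = run_gibbs(region, SamplerConfig(engine="naive", **base))
        assert np.array_equal(d_sparse.p_samples, d_naive.p_samples)
        assert np.array_equal(d_sparse.k_samples, d_naive.k_samples)
        assert np.array_equal(d_sparse.pip, d_naive.pip)
        assert d_sparse.accept_rate == d_naive.accept_rate

    def test_random_permutation_order_also_bit_identical(self, ar1_region_factory):
        region, _, _ = ar1_region_factory(m=25, p_r=0.2, h2_r=0.2, n=2000, seed=32)
        base = dict(n_iter=300, burn_in=50, seed=4, update_order="random-permutation")
        d_sparse = run_gibbs(region, SamplerConfig(engine="sparse", **base))
        d_naive = run_gibbs(region, SamplerConfig(engine="naive", **base))
        assert np.array_equal(d_sparse.p_samples, d_naive.p_samples)

    def test_per_iteration_work_scales_with_k_not_m_squared(self, ar1_region_factory):
        """Sparse engine: ~sum_t K_t * M ops; naive engine: n_iter * M^2."""
        region, _, _ = ar1_region_factory(m=120, p_r=0.05, h2_r=0.05, n=5000, seed=33)
        base = dict(n_iter=200, burn_in=50, seed=3)
        d_sparse = run_gibbs(region, SamplerConfig(engine="sparse", **base))
        d_naive = run_gibbs(region, SamplerConfig(engine="naive", **base))
        m = region.m_r
        assert d_naive.ops == base["n_iter"] * m * m
        mean_k = d_sparse.k_samples.mean()
        # sparse ops grow with the causal count, far below M^2 per iteration
        assert d_sparse.ops < 0.25 * d_naive.ops
        assert d_sparse.ops == pytest.approx(
            base["n_iter"] * m * max(mean_k, 1), rel=1.0
        )

    def test_reproducible_given_seed(self, ar1_region_factory):
        region, _, _ = ar1_region_factory(m=30, seed=34)
        d1 = run_gibbs(region, SamplerConfig(seed=77))
        d2 = run_gibbs(region, SamplerConfig(seed=77))
        assert np.array_equal(d1.p_samples, d2.p_samples)


class TestRunGibbsContracts:
    def test_draw_counts_and_ranges(self, ar1_region_factory):
        region, _, _ = ar1_region_factory(m=20, seed=41)
        cfg = SamplerConfig(n_iter=500, burn_in=100, seed=6)
        d = run_gibbs(region, cfg)
        assert len(d.p_samples) == 400
        assert np.all((d.p_samples > 0) & (d.p_samples < 1))
        assert np.all((d.pip >= 0) & (d.pip <= 1))
        assert np.all(d.k_samples >= 0)

    def test_mh_acceptance_strictly_between_zero_and_one(self, ar1_region_factory):
        region, _, _ = ar1_region_factory(m=50, p_r=0.1, h2_r=0.1, n=2000, seed=42)
        d = run_gibbs(region, SamplerConfig(n_iter=1000, burn_in=250, seed=8))
        assert 0.0 < d.accept_rate < 1.0

    def test_invalid_model_inputs_rejected(self, ar1_region_factory):
        region, _, _ = ar1_region_factory(m=5, seed=43)
        bad = region.with_inputs(n=region.n, h2_r=1.5)
        with pytest.raises(Exception):
            run_gibbs(bad, SamplerConfig())
        bad2 = region.with_inputs(n=-5, h2_r=0.1)
        with pytest.raises(Exception):
            run_gibbs(bad2, SamplerConfig())
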