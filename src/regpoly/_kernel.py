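"""Compiled inner loop of the Gibbs sampler.

Both engines live in one kernel so that their arithmetic is literally
identical and only the bookkeeping differs:

* sparse engine: a sorted array of causal indices is maintained
  incrementally, so each per-SNP update costs O(K_r) and one iteration
  costs O(K_r M_r);
* naive engine: the causal set is rediscovered by scanning all M_r causal
  statuses at every SNP update, so one iteration costs O(M_r^2).

The residual inner product r_m^T A_{.m} is accumulated over causal SNPs in
ascending index order in both engines, so chains from the two engines are
bit-identical under a shared seed.

The kernel uses numba's own (numpy legacy) RNG, seeded once per run.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_chain"]

_TWO_PI = 2.0 * math.pi


@njit(cache=True)
def _betaln(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def _beta_logpdf(x: float, a: float, b: float) -> float:
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x) - _betaln(a, b)


@njit(cache=True)
def _clamp(p: float, lo: float, hi: float) -> float:
    if p < lo:
        return lo
    if p > hi:
        return hi
    return p


@njit(cache=True)
def _log_conditional_p(
    p: float,
    k: int,
    m_r: int,
    sumsq_gamma: float,
    h2_r: float,
    alpha: float,
    p_lo: float,
    p_hi: float,
) -> float:
    """Unnormalized log conditional density of p given (c, gamma).

    Beta(alpha, alpha) prior + Bernoulli likelihood of the causal statuses +
    Gaussian slab terms for the causal effects; sigma_g^2 = h2/(M * p) with p
    clamped to [p_lo, p_hi] so the variance stays finite at the endpoints.
    """
    if p <= 0.0 or p >= 1.0:
        return -np.inf
    lp = math.log(p)
    l1p = math.log1p(-p)
    out = (alpha - 1.0) * (lp + l1p) + k * lp + (m_r - k) * l1p
    if k > 0:
        pc = _clamp(p, p_lo, p_hi)
        sg2 = h2_r / (m_r * pc)
        out += -0.5 * k * math.log(_TWO_PI * sg2) - sumsq_gamma / (2.0 * sg2)
    return out


@njit(cache=True)
def run_chain(
    b,
    gram,
    diag_gram,
    h2_r,
    sigma_e2,
    alpha,
    proposal_c,
    n_iter,
    burn_in,
    c0,
    gamma0,
    p0,
    seed,
    naive,
    random_order,
    bf_log_coeff,
):
    """Run the full MCMC chain for one region.

    ``bf_log_coeff`` is the coefficient of log(sigma_m^2/sigma_g^2) in the
    log Bayes factor of the inclusion probability: 0.5 for the exact
    spike-and-slab marginalization, 1.0 for the conservative variant that
    down-weights borderline inclusions.

    Returns (p_draws, k_draws, pip, n_accept, ops) where ops counts the
    residual-sum accumulation steps (the complexity-determining work).
    """
    np.random.seed(seed)
    m_r = b.shape[0]
    c = c0.copy()
    gamma = gamma0.copy()
    p = p0

    # sorted causal index array (sparse engine bookkeeping)
    idx = np.empty(m_r, dtype=np.int64)
    k = 0
    for m in range(m_r):
        if c[m] == 1:
            idx[k] = m
            k += 1

    p_lo = 1.0 / (10.0 * m_r)
    p_hi = 1.0 - p_lo

    n_keep = n_iter - burn_in
    p_draws = np.empty(n_keep)
    k_draws = np.empty(n_keep, dtype=np.int64)
    pip = np.zeros(m_r)
    n_accept = 0
    ops = np.int64(0)

    order = np.arange(m_r)

    for it in range(n_iter):
        pc = _clamp(p, p_lo, p_hi)
        sg2 = h2_r / (m_r * pc)
        log_prior_odds = math.log(p) - math.log1p(-p)

        if random_order:
            order = np.random.permutation(m_r)

        for j in range(m_r):
            m = order[j]
            # residual inner product r_m^T A_{.m} = b_m - sum_{l != m, c_l=1} G_{ml} gamma_l
            s = 0.0
            if naive:
                for l in range(m_r):
                    if c[l] == 1 and l != m:
                        s += gram[m, l] * gamma[l]
                    ops += 1
            else:
                for t in range(k):
                    l = idx[t]
                    if l != m:
                        s += gram[m, l] * gamma[l]
                    ops += 1
            inner = b[m] - s
            sig2_m = 1.0 / (1.0 / sg2 + diag_gram[m] / sigma_e2)
            mu_m = sig2_m * inner / sigma_e2
            logit_d = (
                log_prior_odds
                + bf_log_coeff * math.log(sig2_m / sg2)
                + mu_m * mu_m / (2.0 * sig2_m)
            )
            if logit_d >= 0.0:
                d = 1.0 / (1.0 + math.exp(-logit_d))
            else:
                e = math.exp(logit_d)
                d = e / (1.0 + e)

            u = np.random.random()
            if u < d:
                new_c = 1
                new_gamma = np.random.normal(mu_m, math.sqrt(sig2_m))
            else:
                new_c = 0
                new_gamma = 0.0

            if new_c == 1 and c[m] == 0:
                # insert m into the sorted causal index array
                pos = k
                for t in range(k):
                    if idx[t] > m:
                        pos = t
                        break
                for t in range(k, pos, -1):
                    idx[t] = idx[t - 1]
                idx[pos] = m
                k += 1
            elif new_c == 0 and c[m] == 1:
                pos = -1
                for t in range(k):
                    if idx[t] == m:
                        pos = t
                        break
                for t in range(pos, k - 1):
                    idx[t] = idx[t + 1]
                k -= 1
            c[m] = new_c
            gamma[m] = new_gamma

        # Metropolis-Hastings update of p with a Beta proposal centered at p
        sumsq = 0.0
        for t in range(k):
            g = gamma[idx[t]]
            sumsq += g * g
        pc = _clamp(p, p_lo, p_hi)
        a1 = alpha + proposal_c * pc
        a2 = alpha + proposal_c * (1.0 - pc)
        p_star = np.random.beta(a1, a2)
        if 0.0 < p_star < 1.0:
            psc = _clamp(p_star, p_lo, p_hi)
            b1 = alpha + proposal_c * psc
            b2 = alpha + proposal_c * (1.0 - psc)
            log_ratio = (
                _log_conditional_p(p_star, k, m_r, sumsq, h2_r, alpha, p_lo, p_hi)
                - _log_conditional_p(p, k, m_r, sumsq, h2_r, alpha, p_lo, p_hi)
                + _beta_logpdf(p, b1, b2)
                - _beta_logpdf(p_star, a1, a2)
            )
            if math.log(np.random.random()) < log_ratio:
                p = p_star
                n_accept += 1

        if it >= burn_in:
            t_keep = it - burn_in
            p_draws[t_keep] = p
            k_draws[t_keep] = k
            for t in range(k):
                pip[idx[t]] += 1.0

    pip /= n_keep
    return p_draws, k_draws, pip, n_accept, ops
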