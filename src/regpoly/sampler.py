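"""MCMC engine for regional polygenicity.

Model, per region r with M_r SNPs:

* causal statuses  c_m ~ Bernoulli(p),
* slab effects     gamma_m ~ N(0, sigma_g^2),  sigma_g^2 = h_r^2 / (M_r p),
* true effects     beta_m = gamma_m c_m,
* whitened GWAS effects  beta_tilde | beta ~ N(A beta, sigma_e^2 I),
  sigma_e^2 = (1 - h_r^2)/N,
* prior            p ~ Beta(alpha, alpha).

Inference alternates a block Gibbs update of (gamma_m, c_m) at every SNP
(the spike component is collapsed: gamma_m is integrated out of the
inclusion probability and non-causal gammas are not represented) with one
random-walk Metropolis-Hastings update of p using a Beta proposal
Beta(alpha + C p, alpha + C (1 - p)) and the standard Hastings correction.

sigma_g^2 = h^2/(M p) diverges as p -> 0, so p is clamped to
[1/(10 M_r), 1 - 1/(10 M_r)] wherever sigma_g^2 or the proposal parameters
are evaluated; the clamp is part of the implemented model and the
enumeration oracle applies it identically.

All densities are evaluated in log space; the Bernoulli inclusion
probability uses the logistic form to avoid overflow of
exp(mu^2 / (2 sigma^2)) at large sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, betaln

from .ld import TransformedRegion

__all__ = [
    "SamplerConfig",
    "SamplerState",
    "PosteriorDraws",
    "ModelConstants",
    "ConfigurationError",
    "model_constants",
    "init_state",
    "slab_conditional",
    "inclusion_prob",
    "update_snp",
    "log_conditional_p",
    "mh_update_p",
    "run_gibbs",
    "enumerate_posterior",
    "EnumeratedPosterior",
    "mc_standard_error",
]


class ConfigurationError(ValueError):
    """Invalid sampler configuration or model constants."""


@dataclass(frozen=True)
class SamplerConfig:
    """Tuning knobs of the MCMC run.

    Defaults: 1000 iterations with a 250-iteration burn-in, Beta(0.2, 0.2)
    prior, proposal concentration C = 10 (effective mixing for the p-chain),
    and causal initialization at |z| >= 3.5.
    """

    n_iter: int = 1000
    burn_in: int = 250
    alpha: float = 0.2
    proposal_c: float = 10.0
    init_z_threshold: float = 3.5
    seed: int = 0
    update_order: str = "fixed-ascending"
    engine: str = "sparse"
    inclusion_bf: str = "exact"

    @property
    def bf_log_coeff(self) -> float:
        return 0.5 if self.inclusion_bf == "exact" else 1.0

    @classmethod
    def from_file(cls, path, **overrides) -> "SamplerConfig":
        """Load a flat key-value (YAML) sampler config; kwargs override."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ConfigurationError("need n_iter > burn_in >= 0")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.proposal_c <= 0:
            raise ConfigurationError("proposal_c must be positive")
        if self.update_order not in ("fixed-ascending", "random-permutation"):
            raise ConfigurationError(f"unknown update_order {self.update_order!r}")
        if self.engine not in ("sparse", "naive"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")
        if self.inclusion_bf not in ("exact", "conservative"):
            raise ConfigurationError(f"unknown inclusion_bf {self.inclusion_bf!r}")


@dataclass(frozen=True)
class ModelConstants:
    """Variance components at the current polygenicity."""

    sigma_g2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ConfigurationError("variance components must be strictly positive")


def _clamp_p(p: float, m_r: int) -> float:
    lo = 1.0 / (10.0 * m_r)
    return min(max(p, lo), 1.0 - lo)


def model_constants(h2_r: float, n: float, m_r: int, p: float) -> ModelConstants:
    """sigma_g^2 = h_r^2/(M_r p) and sigma_e^2 = (1 - h_r^2)/N.

    p is clamped away from {0, 1} so the slab variance stays finite.
    """
    if not (0.0 < h2_r < 1.0):
        raise ConfigurationError("h2_r must lie in (0, 1)")
    if n <= 0:
        raise ConfigurationError("sample size must be positive")
    pc = _clamp_p(p, m_r)
    return ModelConstants(sigma_g2=h2_r / (m_r * pc), sigma_e2=(1.0 - h2_r) / n)


@dataclass
class SamplerState:
    """Current MCMC state: causal statuses, slab effects, p, cached residual.

    ``gamma`` is stored as 0 where c = 0 (the spike component is collapsed
    out of the target density).  ``residual`` caches
    rho = beta_tilde - A (gamma o c) and is updated incrementally; it can be
    recomputed from scratch for integrity checks.
    """

    c: np.ndarray
    gamma: np.ndarray
    p: float
    residual: np.ndarray
    k: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.k < 0:
            self.k = int(self.c.sum())

    def causal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.c == 1)

    def residual_from_scratch(self, region: TransformedRegion) -> np.ndarray:
        return region.beta_tilde - region.ld.sqrt_rows @ (self.gamma * self.c)

    def check_residual(self, region: TransformedRegion, tol: float = 1e-8) -> float:
        err = float(np.max(np.abs(self.residual - self.residual_from_scratch(region))))
        if err > tol:
            raise RuntimeError(f"cached residual drifted by {err:.3g} (tol {tol:g})")
        return err


def init_state(
    z_scores: np.ndarray,
    config: SamplerConfig,
    region: TransformedRegion,
    rng: np.random.Generator | None = None,
) -> SamplerState:
    """Initialize (c, gamma, p) from GWAS z-scores.

    c_m = 1 iff |z_m| >= threshold; p0 = mean(c) floored at 1/M_r and capped
    at 1 - 1/M_r; each initial causal effect is drawn from the slab prior at
    p0; the residual is built from the initial state.
    """
    z = np.asarray(z_scores, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m_r = region.m_r
    c = (np.abs(z) >= config.init_z_threshold).astype(np.int64)
    p0 = float(np.clip(c.mean(), 1.0 / m_r, 1.0 - 1.0 / m_r))
    consts = model_constants(region.h2_r, region.n, m_r, p0)
    gamma = np.zeros(m_r)
    n_causal = int(c.sum())
    if n_causal:
        gamma[c == 1] = rng.normal(0.0, math.sqrt(consts.sigma_g2), size=n_causal)
    residual = region.beta_tilde - region.ld.sqrt_rows @ (gamma * c)
    return SamplerState(c=c, gamma=gamma, p=p0, residual=residual)


def slab_conditional(
    m: int,
    state: SamplerState,
    region: TransformedRegion,
    constants: ModelConstants | None = None,
) -> tuple[float, float]:
    """Posterior mean and variance of gamma_m given c_m = 1 and the rest.

    1/sigma_m^2 = 1/sigma_g^2 + G_mm/sigma_e^2 and
    mu_m = (sigma_m^2/sigma_e^2) * r_m^T A_{.m}, where the inner product is
    computed sparsely as b_m - sum_{l != m, c_l = 1} G_{ml} gamma_l at cost
    O(K_r).
    """
    if constants is None:
        constants = model_constants(region.h2_r, region.n, region.m_r, state.p)
    gram = region.ld.gram()
    causal = state.causal_indices()
    causal = causal[causal != m]
    s = float(gram[m, causal] @ state.gamma[causal]) if causal.size else 0.0
    inner = region.b[m] - s
    sig2_m = 1.0 / (1.0 / constants.sigma_g2 + gram[m, m] / constants.sigma_e2)
    mu_m = sig2_m * inner / constants.sigma_e2
    return mu_m, sig2_m


def inclusion_prob(
    mu_m: float,
    sigma2_m: float,
    sigma_g2: float,
    p: float,
    bf_log_coeff: float = 0.5,
) -> float:
    """Bernoulli parameter d_m for c_m, computed in log space.

    Exact form (``bf_log_coeff = 0.5``, the spike-and-slab marginalization):

    d_m = logistic( log(p/(1-p)) + (1/2) log(sigma_m^2/sigma_g^2)
                    + mu_m^2 / (2 sigma_m^2) ).

    ``bf_log_coeff = 1.0`` gives the conservative variant, which scales the
    inclusion Bayes factor by an extra sqrt(sigma_m^2/sigma_g^2) < 1 and so
    suppresses weakly supported inclusions.
    """
    if p >= 1.0:
        return 1.0
    if p <= 0.0:
        return 0.0
    logit = (
        math.log(p / (1.0 - p))
        + bf_log_coeff * math.log(sigma2_m / sigma_g2)
        + mu_m * mu_m / (2.0 * sigma2_m)
    )
    if logit >= 0:
        return 1.0 / (1.0 + math.exp(-logit))
    e = math.exp(logit)
    return e / (1.0 + e)


def update_snp(
    m: int,
    state: SamplerState,
    region: TransformedRegion,
    rng: np.random.Generator,
    constants: ModelConstants | None = None,
    bf_log_coeff: float = 0.5,
) -> SamplerState:
    """Block Gibbs update of (gamma_m, c_m); mutates and returns the state.

    Draws c_m ~ Bernoulli(d_m); if causal, gamma_m ~ N(mu_m, sigma_m^2),
    else gamma_m = 0.  The cached residual is updated incrementally by
    -A_{.m} * delta(gamma_m c_m).
    """
    if constants is None:
        constants = model_constants(region.h2_r, region.n, region.m_r, state.p)
    mu_m, sig2_m = slab_conditional(m, state, region, constants)
    d = inclusion_prob(mu_m, sig2_m, constants.sigma_g2, state.p, bf_log_coeff)
    old = state.gamma[m] * state.c[m]
    if rng.random() < d:
        new_c = 1
        new_gamma = rng.normal(mu_m, math.sqrt(sig2_m))
    else:
        new_c = 0
        new_gamma = 0.0
    delta = new_gamma * new_c - old
    if delta != 0.0:
        state.residual -= region.ld.sqrt_rows[:, m] * delta
    state.k += new_c - state.c[m]
    state.c[m] = new_c
    state.gamma[m] = new_gamma
    return state


def log_conditional_p(
    p: float,
    k: int,
    m_r: int,
    gamma_causal: np.ndarray,
    h2_r: float,
    alpha: float,
) -> float:
    """Unnormalized log conditional density of p given (c, gamma).

    (alpha-1) log p + (alpha-1) log(1-p) + k log p + (M_r - k) log(1-p)
    plus the Gaussian slab log-densities of the causal effects at
    sigma_g^2 = h_r^2/(M_r p) (p clamped).  Only causal gamma terms enter:
    non-causal gammas are marginalized out of the state representation.
    """
    if not (0.0 < p < 1.0):
        return -np.inf
    lp = math.log(p)
    l1p = math.log1p(-p)
    out = (alpha - 1.0) * (lp + l1p) + k * lp + (m_r - k) * l1p
    if k > 0:
        gamma_causal = np.asarray(gamma_causal, dtype=float)
        sg2 = h2_r / (m_r * _clamp_p(p, m_r))
        out += -0.5 * k * math.log(2.0 * math.pi * sg2) - float(
            gamma_causal @ gamma_causal
        ) / (2.0 * sg2)
    return out


def _beta_logpdf(x: float, a: float, b: float) -> float:
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x) - float(betaln(a, b))


def proposal_params(p: float, config: SamplerConfig, m_r: int) -> tuple[float, float]:
    """Parameters of the Beta proposal Beta(alpha + C p, alpha + C (1-p))."""
    pc = _clamp_p(p, m_r)
    return (
        config.alpha + config.proposal_c * pc,
        config.alpha + config.proposal_c * (1.0 - pc),
    )


def mh_update_p(
    state: SamplerState,
    region: TransformedRegion,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> bool:
    """One Metropolis-Hastings update of p; returns the accept flag.

    Acceptance probability min(1, exp(dlog target + dlog proposal)) with the
    Hastings correction for the asymmetric Beta proposal.
    """
    m_r = region.m_r
    a1, a2 = proposal_params(state.p, config, m_r)
    p_star = float(rng.beta(a1, a2))
    if not (0.0 < p_star < 1.0):
        return False
    gamma_causal = state.gamma[state.c == 1]
    b1, b2 = proposal_params(p_star, config, m_r)
    log_ratio = (
        log_conditional_p(p_star, state.k, m_r, gamma_causal, region.h2_r, config.alpha)
        - log_conditional_p(state.p, state.k, m_r, gamma_causal, region.h2_r, config.alpha)
        + _beta_logpdf(state.p, b1, b2)
        - _beta_logpdf(p_star, a1, a2)
    )
    if math.log(rng.random()) < log_ratio:
        state.p = p_star
        return True
    return False


@dataclass
class PosteriorDraws:
    """Retained post-burn-in MCMC draws and per-SNP inclusion frequencies."""

    p_samples: np.ndarray
    k_samples: np.ndarray
    pip: np.ndarray
    accept_rate: float
    m_r: int
    engine: str = "sparse"
    ops: int = 0

    @property
    def p_mean(self) -> float:
        return float(self.p_samples.mean())

    @property
    def p_sd(self) -> float:
        return float(self.p_samples.std(ddof=1))


def _derive_seeds(seed: int) -> tuple[int, int]:
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0]), int(state[1]) & 0x7FFFFFFF


def run_gibbs(
    region: TransformedRegion,
    config: SamplerConfig | None = None,
    z_scores: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run the full sampler for one region and return the retained draws.

    Each iteration sweeps one block (gamma, c) update over all SNPs (fixed
    ascending order by default) followed by one Metropolis-Hastings update of
    p.  With the sparse engine the per-iteration cost is O(K_r M_r).

    When ``z_scores`` is omitted they are derived from the (projected)
    marginal effects as z = b * sqrt(N), the standardized-scale identity.
    """
    from ._kernel import run_chain

    if config is None:
        config = SamplerConfig()
    if region.h2_r is None or not (0.0 < region.h2_r < 1.0):
        raise ConfigurationError("region.h2_r must lie in (0, 1)")
    if region.n is None or region.n <= 0:
        raise ConfigurationError("region.n must be positive")

    init_seed, chain_seed = _derive_seeds(config.seed)
    rng = np.random.default_rng(init_seed)
    if z_scores is None:
        z_scores = region.b * math.sqrt(region.n)
    state = init_state(z_scores, config, region, rng=rng)

    gram = np.ascontiguousarray(region.ld.gram())
    p_draws, k_draws, pip, n_accept, ops = run_chain(
        np.ascontiguousarray(region.b),
        gram,
        np.ascontiguousarray(np.diag(gram)),
        float(region.h2_r),
        float(region.sigma_e2),
        float(config.alpha),
        float(config.proposal_c),
        config.n_iter,
        config.burn_in,
        state.c.astype(np.int64),
        state.gamma.astype(np.float64),
        float(state.p),
        chain_seed,
        config.engine == "naive",
        config.update_order == "random-permutation",
        config.bf_log_coeff,
    )
    return PosteriorDraws(
        p_samples=p_draws,
        k_samples=k_draws,
        pip=pip,
        accept_rate=n_accept / config.n_iter,
        m_r=region.m_r,
        engine=config.engine,
        ops=int(ops),
    )


def mc_standard_error(x: np.ndarray, n_batches: int = 25) -> float:
    """Batch-means Monte-Carlo standard error of the mean of a chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_batches = min(n_batches, max(2, n // 10))
    size = n // n_batches
    means = x[: n_batches * size].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


@dataclass
class EnumeratedPosterior:
    """Exact posterior over (causal configurations x p) for a small region."""

    p_grid: np.ndarray
    p_density: np.ndarray  # density on the interior grid (normalized with tails)
    tail_mass: tuple[float, float]
    p_mean: float
    p_sd: float
    pip: np.ndarray
    config_probs: dict[tuple[int, ...], float]


def _config_loglik(
    beta_ss: float,
    rank: int,
    b_c: np.ndarray,
    g_cc: np.ndarray,
    sigma_e2: float,
    sigma_g2: float,
) -> float:
    """log N(beta_tilde; 0, sigma_e^2 I + sigma_g^2 A_C A_C^T) via Woodbury.

    Needs only ||beta_tilde||^2, b restricted to the configuration and the
    configuration's Gram block, so it shares the sampler's precomputations.
    """
    k = len(b_c)
    if k == 0:
        return -0.5 * (rank * math.log(2.0 * math.pi * sigma_e2) + beta_ss / sigma_e2)
    mat = (sigma_e2 / sigma_g2) * np.eye(k) + g_cc
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD Woodbury block")
    quad = beta_ss - float(b_c @ np.linalg.solve(mat, b_c))
    logdet_full = rank * math.log(sigma_e2) + logdet - k * math.log(
        sigma_e2 / sigma_g2
    )
    return -0.5 * (rank * math.log(2.0 * math.pi) + logdet_full + quad / sigma_e2)


def enumerate_posterior(
    region: TransformedRegion,
    alpha: float = 0.2,
    n_grid: int = 2001,
    max_m: int = 12,
) -> EnumeratedPosterior:
    """Exact posterior for M_r <= 12 by enumerating 2^M_r configurations.

    For each configuration C, gamma is integrated out analytically:
    beta_tilde | C, p ~ N(0, sigma_e^2 I + sigma_g^2(p) A_C A_C^T); the joint
    weight is that likelihood times p^K (1-p)^{M-K} Beta(p; alpha, alpha).
    The p-integral is midpoint quadrature on [p_lo, p_hi] (where sigma_g^2
    varies) plus analytic incomplete-Beta tail terms (where sigma_g^2 is
    clamped constant, exactly as in the sampler).
    """
    m_r = region.m_r
    if m_r > max_m:
        raise ValueError(f"enumeration limited to M_r <= {max_m}, got {m_r}")
    h2 = region.h2_r
    sigma_e2 = region.sigma_e2
    gram = region.ld.gram()
    b = region.b
    beta_ss = region.beta_tilde_ss
    rank = region.ld.rank

    p_lo = 1.0 / (10.0 * m_r)
    p_hi = 1.0 - p_lo
    step = (p_hi - p_lo) / n_grid
    p_grid = p_lo + (np.arange(n_grid) + 0.5) * step
    sg2_grid = h2 / (m_r * p_grid)

    log_weights = []  # per config: (loglik arrays / tail stats)
    configs = []
    # accumulate in log space with a global max shift at the end
    grid_logw = np.full((2**m_r, n_grid), -np.inf)
    tail_logw = np.full((2**m_r, 2, 3), -np.inf)  # (config, tail, moment 0/1/2)

    for code in range(2**m_r):
        members = [m for m in range(m_r) if (code >> m) & 1]
        k = len(members)
        idx = np.array(members, dtype=int)
        b_c = b[idx]
        g_cc = gram[np.ix_(idx, idx)]

        if k == 0:
            ll_grid = np.full(n_grid, _config_loglik(beta_ss, rank, b_c, g_cc, sigma_e2, 1.0))
            ll_lo = ll_grid[0]
            ll_hi = ll_grid[0]
        else:
            ll_grid = np.array(
                [
                    _config_loglik(beta_ss, rank, b_c, g_cc, sigma_e2, sg2)
                    for sg2 in sg2_grid
                ]
            )
            ll_lo = _config_loglik(beta_ss, rank, b_c, g_cc, sigma_e2, h2 / (m_r * p_lo))
            ll_hi = _config_loglik(beta_ss, rank, b_c, g_cc, sigma_e2, h2 / (m_r * p_hi))

        a_beta = k + alpha
        b_beta = m_r - k + alpha
        grid_logw[code] = (
            ll_grid
            + (a_beta - 1.0) * np.log(p_grid)
            + (b_beta - 1.0) * np.log1p(-p_grid)
            + math.log(step)
        )
        # analytic tails: integral of p^{a-1+j} (1-p)^{b-1} over the tail,
        # j = 0, 1, 2 for mass / mean / second moment
        for j in range(3):
            lb = float(betaln(a_beta + j, b_beta))
            frac_lo = float(betainc(a_beta + j, b_beta, p_lo))
            frac_hi = 1.0 - float(betainc(a_beta + j, b_beta, p_hi))
            if frac_lo > 0:
                tail_logw[code, 0, j] = ll_lo + lb + math.log(frac_lo)
            if frac_hi > 0:
                tail_logw[code, 1, j] = ll_hi + lb + math.log(frac_hi)
        configs.append(tuple(members))

    shift = max(float(grid_logw.max()), float(tail_logw[:, :, 0].max()))
    gw = np.exp(grid_logw - shift)
    tw = np.exp(tail_logw - shift)

    mass_per_config = gw.sum(axis=1) + tw[:, :, 0].sum(axis=1)
    z = float(mass_per_config.sum())
    mean_num = float((gw * p_grid).sum() + tw[:, :, 1].sum())
    m2_num = float((gw * p_grid**2).sum() + tw[:, :, 2].sum())
    p_mean = mean_num / z
    p_sd = math.sqrt(max(m2_num / z - p_mean**2, 0.0))

    pip = np.zeros(m_r)
    for code, members in enumerate(configs):
        for m in members:
            pip[m] += mass_per_config[code]
    pip /= z

    config_probs = {
        configs[code]: float(mass_per_config[code] / z) for code in range(2**m_r)
    }
    p_density = gw.sum(axis=0) / (z * step)
    tail_mass = (float(tw[:, 0, 0].sum() / z), float(tw[:, 1, 0].sum() / z))
    return EnumeratedPosterior(
        p_grid=p_grid,
        p_density=p_density,
        tail_mass=tail_mass,
        p_mean=p_mean,
        p_sd=p_sd,
        pip=pip,
        config_probs=config_probs,
    )
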