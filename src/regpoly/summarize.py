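"""Posterior summaries: regional reports, genome-wide aggregation, regressions.

A region is called nonzero when posterior mean - 2 x posterior SD of p_r is
above 0.  Genome-wide polygenicity is the SNP-count-weighted mean of regional
posterior means (equivalently, summed expected causal counts divided by the
total SNP count), with credible intervals formed by resampling retained draws
independently across regions (the regional model assumes no cross-region
correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .sampler import PosteriorDraws

__all__ = [
    "RegionReport",
    "GenomeReport",
    "summarize_region",
    "aggregate_genome",
    "threshold_proportions",
    "regress_h2_on_counts",
]


@dataclass
class RegionReport:
    """Posterior summary of one region's polygenicity and causal count."""

    region_id: str
    m_r: int
    h2_r: float | None
    p_mean: float
    p_sd: float
    p_ci95: tuple[float, float]
    mc_mean: float
    mc_sd: float
    mc_ci95: tuple[float, float]
    nonzero: bool

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_region(
    draws: PosteriorDraws | np.ndarray,
    m_r: int,
    h2_r: float | None = None,
    region_id: str = "region",
) -> RegionReport:
    """Posterior mean, SD, equal-tailed 95% CI and the nonzero call.

    The causal-count summaries are M_r * p per draw (an exact per-draw
    identity, so mc fields are the p fields scaled by M_r).  The nonzero rule
    is p_mean - 2 p_sd > 0.
    """
    p = draws.p_samples if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if p.size == 0:
        raise ValueError("no retained draws to summarize")
    p_mean = float(p.mean())
    p_sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    lo, hi = np.percentile(p, [2.5, 97.5])
    return RegionReport(
        region_id=region_id,
        m_r=m_r,
        h2_r=h2_r,
        p_mean=p_mean,
        p_sd=p_sd,
        p_ci95=(float(lo), float(hi)),
        mc_mean=m_r * p_mean,
        mc_sd=m_r * p_sd,
        mc_ci95=(m_r * float(lo), m_r * float(hi)),
        nonzero=bool(p_mean - 2.0 * p_sd > 0.0),
    )


@dataclass
class GenomeReport:
    """Genome-wide aggregation of regional posteriors."""

    n_regions: int
    total_snps: int
    percent_regions_nonzero: float
    p_gw_mean: float
    p_gw_ci95: tuple[float, float]
    mc_gw_mean: float
    mc_gw_ci95: tuple[float, float]
    threshold_props: dict[int, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["threshold_props"] = {str(k): v for k, v in self.threshold_props.items()}
        return d


def aggregate_genome(
    reports: list[RegionReport],
    draws_by_region: list[np.ndarray],
    n_resample: int = 10_000,
    k_list: tuple[int, ...] = (1, 5, 50),
    rng: np.random.Generator | int | None = None,
) -> GenomeReport:
    """Aggregate regional posteriors into a genome-wide report.

    Genome-wide polygenicity = sum_r M_r E[p_r] / sum_r M_r and the expected
    causal count is its numerator.  Credible intervals come from
    ``n_resample`` independent resamples of each region's retained chain
    (regions are assumed posterior-independent: disjoint SNP sets).
    """
    if len(reports) != len(draws_by_region):
        raise ValueError("reports and draws lists differ in length")
    ids = [r.region_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping regions: duplicate region ids")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = np.array([r.m_r for r in reports], dtype=float)
    total = float(m.sum())
    mc_mean = float(sum(r.m_r * r.p_mean for r in reports))

    mc_resamples = np.zeros(n_resample)
    for m_r, draws in zip(m, draws_by_region):
        draws = np.asarray(draws, dtype=float)
        picks = rng.integers(0, draws.size, size=n_resample)
        mc_resamples += m_r * draws[picks]
    mc_lo, mc_hi = np.percentile(mc_resamples, [2.5, 97.5])

    return GenomeReport(
        n_regions=len(reports),
        total_snps=int(total),
        percent_regions_nonzero=100.0 * float(np.mean([r.nonzero for r in reports])),
        p_gw_mean=mc_mean / total,
        p_gw_ci95=(float(mc_lo) / total, float(mc_hi) / total),
        mc_gw_mean=mc_mean,
        mc_gw_ci95=(float(mc_lo), float(mc_hi)),
        threshold_props=threshold_proportions(reports, k_list),
    )


def threshold_proportions(
    reports: list[RegionReport],
    k_list: tuple[int, ...] = (1, 5, 50),
    rule: str = "mean2sd",
    draws_by_region: list[np.ndarray] | None = None,
    prob: float = 0.95,
) -> dict[int, float]:
    """Fraction of regions whose posterior supports >= k causal SNPs.

    Default rule mirrors the nonzero call: mc_mean - 2 mc_sd >= k for k > 1
    and the nonzero flag itself for k = 1.  Alternative rule ``"posterior"``
    requires posterior probability >= ``prob`` that the causal count exceeds
    k (needs the retained p draws).
    """
    if not reports:
        raise ValueError("no region reports")
    out: dict[int, float] = {}
    for k in k_list:
        if rule == "mean2sd":
            if k <= 1:
                hits = [r.nonzero for r in reports]
            else:
                hits = [r.mc_mean - 2.0 * r.mc_sd >= k for r in reports]
        elif rule == "posterior":
            if draws_by_region is None:
                raise ValueError("posterior rule needs draws_by_region")
            hits = [
                float(np.mean(r.m_r * np.asarray(d) >= k)) >= prob
                for r, d in zip(reports, draws_by_region)
            ]
        else:
            raise ValueError(f"unknown rule {rule!r}")
        out[k] = float(np.mean(hits))
    return out


@dataclass
class RegressionFit:
    """One OLS fit of regional heritability on counts."""

    predictors: tuple[str, ...]
    slopes: dict[str, float]
    slope_se: dict[str, float]
    r2: float
    pvalues: dict[str, float]
    outliers: np.ndarray  # indices with |studentized residual| > 3


def _fit(y: np.ndarray, x: np.ndarray, names: tuple[str, ...]) -> RegressionFit:
    for j, name in enumerate(names):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"constant predictor: {name}")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictors")
    res = sm.OLS(y, design).fit()
    student = OLSInfluence(res).resid_studentized_external
    return RegressionFit(
        predictors=names,
        slopes={n: float(res.params[j + 1]) for j, n in enumerate(names)},
        slope_se={n: float(res.bse[j + 1]) for j, n in enumerate(names)},
        r2=float(res.rsquared),
        pvalues={n: float(res.pvalues[j + 1]) for j, n in enumerate(names)},
        outliers=np.flatnonzero(np.abs(student) > 3.0),
    )


def regress_h2_on_counts(
    h2_by_region: np.ndarray,
    m_by_region: np.ndarray,
    mc_by_region: np.ndarray,
) -> dict[str, RegressionFit]:
    """OLS of regional heritability on SNP counts and causal-SNP counts.

    Three fits: h2 ~ M_r, h2 ~ Mc_r, and h2 ~ M_r + Mc_r, each with slopes,
    R^2, p-values and outlier flags at |externally studentized residual| > 3.
    """
    h2 = np.asarray(h2_by_region, dtype=float)
    m = np.asarray(m_by_region, dtype=float)
    mc = np.asarray(mc_by_region, dtype=float)
    if not (len(h2) == len(m) == len(mc)):
        raise ValueError("inputs differ in length")
    if len(h2) < 10:
        raise ValueError("need at least 10 regions for the regression")
    return {
        "m": _fit(h2, m[:, None], ("m",)),
        "mc": _fit(h2, mc[:, None], ("mc",)),
        "m+mc": _fit(h2, np.column_stack([m, mc]), ("m", "mc")),
    }
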