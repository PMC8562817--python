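"""LD (linkage disequilibrium) matrices and the whitening transform.

GWAS marginal effects within a region are correlated through the SNP
correlation matrix V.  The sampler works with whitened effects
``beta_tilde = V^{-1/2} beta_hat``, whose residual noise is independent
across coordinates, and with two precomputed quantities:

* ``b_m = beta_tilde^T A_{.m}`` where ``A`` plays the role of V^{1/2}
  (rows indexed by retained eigen-component, columns by SNP), and
* the Gram entries ``A_{.l}^T A_{.m}``, which equal ``V_{lm}`` whenever the
  factorization is full rank.

Because of the Gram identity, the per-SNP Gibbs updates never need A itself
beyond ``b`` — only entries of V — which is what makes the sparse sampler's
O(K_r M_r) arithmetic possible.

Rank-deficient V (duplicate SNPs, finite reference panels) is handled by
eigenvalue truncation: components with eigenvalue below ``tol * lambda_max``
are dropped and the model ``beta_tilde | beta ~ N(A beta, sigma_e^2 I_rank)``
is exact on the retained subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LDMatrix",
    "LDFactor",
    "TransformedRegion",
    "LDValidationError",
    "DegenerateLDError",
    "compute_ld",
    "factorize",
    "whiten",
    "standardize_columns",
    "standardize_dosages",
]


class LDValidationError(ValueError):
    """An LD matrix violates its structural invariants."""


class DegenerateLDError(ValueError):
    """An LD matrix has no positive eigenvalue."""


@dataclass
class LDMatrix:
    """A regional SNP correlation matrix (dimensionless, unit diagonal)."""

    values: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise LDValidationError("LD matrix must be square")
        if self.snp_ids is not None and len(self.snp_ids) != self.values.shape[0]:
            raise LDValidationError("snp_ids length does not match matrix size")

    @property
    def m_r(self) -> int:
        return self.values.shape[0]

    def validate(
        self,
        sym_tol: float = 1e-8,
        diag_tol: float = 1e-6,
        range_tol: float = 1e-8,
    ) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise LDValidationError("LD matrix contains non-finite entries")
        if np.max(np.abs(v - v.T)) > sym_tol:
            raise LDValidationError("LD matrix is not symmetric")
        if np.max(np.abs(np.diag(v) - 1.0)) > diag_tol:
            raise LDValidationError("LD matrix diagonal deviates from 1")
        if np.max(np.abs(v)) > 1.0 + range_tol:
            raise LDValidationError("LD matrix has entries outside [-1, 1]")


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Column-standardize a numeric matrix to mean 0 and variance 1 exactly."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"column {bad} is constant and cannot be standardized")
    return (x - mu) / sd


def standardize_dosages(g: np.ndarray) -> np.ndarray:
    """Standardize minor-allele dosages g in {0,1,2} via x = (g-2f)/sqrt(2f(1-f)).

    f is the in-sample minor allele frequency, estimated as mean(g)/2.
    """
    g = np.asarray(g, dtype=float)
    f = g.mean(axis=0) / 2.0
    if np.any((f <= 0) | (f >= 1)):
        bad = int(np.flatnonzero((f <= 0) | (f >= 1))[0])
        raise ValueError(f"column {bad} is monomorphic (allele frequency 0 or 1)")
    return (g - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def compute_ld(
    genotypes: np.ndarray,
    snp_ids: list[str] | None = None,
    std_tol: float = 1e-3,
) -> LDMatrix:
    """Compute the regional LD matrix V = X^T X / N from standardized genotypes.

    The input must already be (approximately) column-standardized; columns are
    re-centered and re-scaled exactly before the cross-product so that V is
    the exact Pearson correlation matrix with a unit diagonal.

    Parameters
    ----------
    genotypes
        N x M_r matrix, columns standardized to mean 0 and variance 1 within
        ``std_tol``.
    """
    x = np.asarray(genotypes, dtype=float)
    if x.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals to compute LD")
    mu = x.mean(axis=0)
    var = x.var(axis=0)
    if np.max(np.abs(mu)) > std_tol:
        bad = int(np.argmax(np.abs(mu)))
        raise ValueError(
            f"column {bad} is not standardized: mean {mu[bad]:.3g} exceeds tolerance"
        )
    if np.max(np.abs(var - 1.0)) > 10 * std_tol:
        bad = int(np.argmax(np.abs(var - 1.0)))
        raise ValueError(
            f"column {bad} is not standardized: variance {var[bad]:.3g} "
            "deviates from 1 beyond tolerance"
        )
    xs = (x - mu) / np.sqrt(var)
    v = xs.T @ xs / n
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 1.0)
    return LDMatrix(values=v, snp_ids=snp_ids)


@dataclass
class LDFactor:
    """Eigen-factorization of an LD matrix.

    ``sqrt_rows`` is the rank x M_r matrix A with A^T A = V on the retained
    subspace; column A_{.m} plays the role of column m of V^{1/2}.
    ``inv_sqrt`` is the rank x M_r whitening operator V^{-1/2} (pseudo-inverse
    square root on the retained subspace).
    """

    sqrt_rows: np.ndarray
    inv_sqrt: np.ndarray
    eigenvalues: np.ndarray
    rank: int
    tol: float
    snp_ids: list[str] | None = None
    _source: np.ndarray | None = field(default=None, repr=False)
    _gram: np.ndarray | None = field(default=None, repr=False)

    @property
    def m_r(self) -> int:
        return self.sqrt_rows.shape[1]

    def gram(self) -> np.ndarray:
        """Gram matrix G with G_{lm} = A_{.l}^T A_{.m}.

        Equals V exactly at full rank (returned without recomputation);
        computed as A^T A when components were truncated.
        """
        if self._gram is None:
            if self.rank == self.m_r and self._source is not None:
                self._gram = self._source
            else:
                self._gram = self.sqrt_rows.T @ self.sqrt_rows
        return self._gram

    def apply_sqrt(self, x: np.ndarray) -> np.ndarray:
        """A @ x: map an M_r-vector of true effects into the whitened space."""
        return self.sqrt_rows @ x

    def unwhiten(self, beta_tilde: np.ndarray) -> np.ndarray:
        """A^T @ beta_tilde: recover beta_hat (exactly, when full rank)."""
        return self.sqrt_rows.T @ beta_tilde


def factorize(ld: LDMatrix, tol: float = 1e-8) -> LDFactor:
    """Eigendecompose V = U L U^T and build A = L_+^{1/2} U_+^T.

    Eigenvalues below ``tol * lambda_max`` are dropped; the retained rank is
    recorded.  Raises :class:`DegenerateLDError` when no eigenvalue is
    positive.
    """
    ld.validate()
    w, u = np.linalg.eigh(ld.values)
    lmax = w[-1]
    if lmax <= 0:
        raise DegenerateLDError("LD matrix has no positive eigenvalue")
    keep = w >= tol * lmax
    wk = w[keep]
    uk = u[:, keep]
    sqrt_w = np.sqrt(wk)
    a = sqrt_w[:, None] * uk.T
    inv_sqrt = (1.0 / sqrt_w)[:, None] * uk.T
    return LDFactor(
        sqrt_rows=np.ascontiguousarray(a),
        inv_sqrt=np.ascontiguousarray(inv_sqrt),
        eigenvalues=wk,
        rank=int(keep.sum()),
        tol=tol,
        snp_ids=ld.snp_ids,
        _source=ld.values,
    )


@dataclass
class TransformedRegion:
    """One region's whitened GWAS effects plus sampler precomputations.

    ``beta_tilde`` is the rank-length whitened effect vector; ``b`` is the
    M_r-length vector b_m = beta_tilde^T A_{.m} (equal to the projection of
    beta_hat onto the retained subspace, hence to beta_hat itself at full
    rank).  ``n`` is the GWAS sample size and ``h2_r`` the regional
    SNP-heritability; the whitened residual noise variance is
    sigma_e^2 = (1 - h2_r)/n.
    """

    beta_tilde: np.ndarray
    b: np.ndarray
    ld: LDFactor
    n: float | None = None
    m_r: int = 0
    h2_r: float | None = None

    def __post_init__(self) -> None:
        if self.m_r == 0:
            self.m_r = self.ld.m_r
        if not np.all(np.isfinite(self.b)):
            raise ValueError("b vector contains non-finite entries")
        if len(self.b) != self.m_r:
            raise ValueError("b vector length does not match region size")

    @property
    def sigma_e2(self) -> float:
        if self.n is None or self.h2_r is None:
            raise ValueError("sigma_e2 requires both n and h2_r")
        return (1.0 - self.h2_r) / self.n

    @property
    def beta_tilde_ss(self) -> float:
        return float(self.beta_tilde @ self.beta_tilde)

    def with_inputs(self, n: float, h2_r: float) -> "TransformedRegion":
        return TransformedRegion(
            beta_tilde=self.beta_tilde,
            b=self.b,
            ld=self.ld,
            n=n,
            m_r=self.m_r,
            h2_r=h2_r,
        )


def whiten(
    beta_hat: np.ndarray,
    ld_factor: LDFactor,
    n: float | None = None,
    h2_r: float | None = None,
) -> TransformedRegion:
    """One-time whitening transform beta_tilde = V^{-1/2} beta_hat.

    Also precomputes b_m = beta_tilde^T A_{.m} for all SNPs.  Performed once
    per region before running the sampler.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_hat.ndim != 1 or beta_hat.shape[0] != ld_factor.m_r:
        raise ValueError(
            f"beta_hat has length {beta_hat.shape[0] if beta_hat.ndim == 1 else beta_hat.shape}, "
            f"expected {ld_factor.m_r}"
        )
    beta_tilde = ld_factor.inv_sqrt @ beta_hat
    b = ld_factor.sqrt_rows.T @ beta_tilde
    return TransformedRegion(
        beta_tilde=beta_tilde,
        b=np.ascontiguousarray(b),
        ld=ld_factor,
        n=n,
        m_r=ld_factor.m_r,
        h2_r=h2_r,
    )
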