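"""Conjugate Bayesian linear model for clusters of expression curves.

Each cluster's stacked observations follow ``Y = B beta + eps`` with
``eps ~ N(0, sigma^2 I)`` under a normal-inverse-gamma prior:
``beta | sigma^2 ~ N(m0, sigma^2 v0 I)`` and
``sigma^2 ~ InvGamma(a0, b0)``. Genes in a cluster share ``beta`` and
``sigma^2``; each contributes its own copy of the basis rows, with rows for
missing samples dropped (no imputation). The marginal likelihood (evidence)
is available in closed multivariate-t form and is the clustering objective.

Only sufficient statistics (X'X, X'Y, Y'Y, n) enter the evidence, so cluster
merges reduce to adding statistics — the property that makes agglomerative
search over thousands of genes cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .errors import UndefinedEvidenceError
from .fourier import FourierBasis


@dataclass(frozen=True)
class NIGPrior:
    """Normal-inverse-gamma prior hyperparameters.

    m0: prior mean of beta (scalar broadcast or vector of basis length).
    v0: prior coefficient scale; prior covariance of beta is ``sigma^2 v0 I``.
    a0, b0: inverse-gamma shape and scale for sigma^2.

    Defaults are weakly informative on log2-ratio data while keeping the
    evidence proper.
    """

    m0: float | np.ndarray = 0.0
    v0: float = 100.0
    a0: float = 0.001
    b0: float = 0.001

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("v0, a0, b0 must all be > 0")

    def mean_vector(self, p: int) -> np.ndarray:
        m0 = np.asarray(self.m0, dtype=float)
        if m0.ndim == 0:
            return np.full(p, float(m0))
        if m0.shape != (p,):
            raise ValueError(f"m0 has shape {m0.shape}, basis needs ({p},)")
        return m0


@dataclass(frozen=True)
class SufficientStats:
    """Gaussian-linear sufficient statistics of one or more stacked genes."""

    n: int
    xtx: np.ndarray
    xty: np.ndarray
    yty: float

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(
            self.n + other.n,
            self.xtx + other.xtx,
            self.xty + other.xty,
            self.yty + other.yty,
        )


@dataclass
class ClusterPosterior:
    """Posterior summary for one cluster of curves.

    ``harmonic_coeffs[h] = (a_h, b_h)`` are exactly the cosine/sine entries of
    ``beta_hat`` for harmonic ``h``; ``sigma2_post`` holds the updated
    inverse-gamma ``(a_n, b_n)``.
    """

    members: tuple[str, ...]
    beta_hat: np.ndarray
    harmonic_coeffs: dict[int, tuple[float, float]]
    sigma2_post: tuple[float, float]
    log_evidence: float
    harmonics: tuple[int, ...]
    stats: SufficientStats = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def size(self) -> int:
        return len(self.members)

    def fitted_curve(self, basis: FourierBasis) -> np.ndarray:
        return basis.matrix @ self.beta_hat


def gene_stats(y: np.ndarray, basis: FourierBasis) -> SufficientStats:
    """Sufficient statistics of one gene, dropping rows with missing values."""
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    x = basis.matrix[obs]
    yo = y[obs]
    return SufficientStats(
        n=int(yo.size),
        xtx=x.T @ x,
        xty=x.T @ yo,
        yty=float(yo @ yo),
    )


def _posterior_parts(stats: SufficientStats, prior: NIGPrior, p: int):
    m0 = prior.mean_vector(p)
    prec = stats.xtx + np.eye(p) / prior.v0
    cho = cho_factor(prec, lower=True)
    rhs = stats.xty + m0 / prior.v0
    m_n = cho_solve(cho, rhs)
    a_n = prior.a0 + stats.n / 2.0
    b_n = prior.b0 + 0.5 * (stats.yty + m0 @ m0 / prior.v0 - m_n @ rhs)
    b_n = max(float(b_n), np.finfo(float).tiny)
    logdet_prec = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return m_n, a_n, b_n, logdet_prec


def log_evidence_stats(stats: SufficientStats, prior: NIGPrior) -> float:
    """Closed-form log marginal likelihood from sufficient statistics."""
    if stats.n == 0:
        raise UndefinedEvidenceError("cluster has no observed values")
    p = stats.xtx.shape[0]
    _, a_n, b_n, logdet_prec = _posterior_parts(stats, prior, p)
    return float(
        -0.5 * stats.n * np.log(2.0 * np.pi)
        - 0.5 * (logdet_prec + p * np.log(prior.v0))
        + prior.a0 * np.log(prior.b0)
        - a_n * np.log(b_n)
        + gammaln(a_n)
        - gammaln(prior.a0)
    )


def log_evidence(y: np.ndarray, basis: FourierBasis, prior: NIGPrior) -> float:
    """Log evidence of stacked observations ``y`` (one or more genes).

    ``y`` may be 1-D (one gene) or 2-D (genes x samples); NaNs are dropped
    row-wise per gene.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    stats = None
    for row in y:
        s = gene_stats(row, basis)
        stats = s if stats is None else stats + s
    if stats is None or stats.n == 0:
        raise UndefinedEvidenceError("no observed values in cluster")
    return log_evidence_stats(stats, prior)


def posterior_from_stats(
    members: tuple[str, ...],
    stats: SufficientStats,
    basis: FourierBasis,
    prior: NIGPrior,
) -> ClusterPosterior:
    if stats.n == 0:
        raise UndefinedEvidenceError("no observed values in cluster")
    p = basis.matrix.shape[1]
    m_n, a_n, b_n, _ = _posterior_parts(stats, prior, p)
    coeffs = {
        h: (float(m_n[2 * i + 1]), float(m_n[2 * i + 2]))
        for i, h in enumerate(basis.harmonics)
    }
    return ClusterPosterior(
        members=tuple(members),
        beta_hat=m_n,
        harmonic_coeffs=coeffs,
        sigma2_post=(float(a_n), float(b_n)),
        log_evidence=log_evidence_stats(stats, prior),
        harmonics=basis.harmonics,
        stats=stats,
    )


def posterior_profile(
    y: np.ndarray,
    basis: FourierBasis,
    prior: NIGPrior,
    members: tuple[str, ...] = ("gene",),
) -> ClusterPosterior:
    """Posterior mean coefficients and variance update for stacked curves.

    ``beta_hat = (B'B + v0^{-1} I)^{-1} (B'Y + v0^{-1} m0)`` over the observed
    rows of every member gene.
    """
    y2 = np.atleast_2d(np.asarray(y, dtype=float))
    stats = None
    for row in y2:
        s = gene_stats(row, basis)
        stats = s if stats is None else stats + s
    assert stats is not None
    if len(members) != y2.shape[0]:
        members = tuple(f"gene_{i + 1}" for i in range(y2.shape[0]))
    return posterior_from_stats(tuple(members), stats, basis, prior)
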