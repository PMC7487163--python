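"""Drift + sampling variance model for ancestry proportions, and the
variance-matching effective-population-size estimator.

Model
-----
An admixed population starts at ancestry proportion ``p0``.  After ``T``
generations of neutral Wright-Fisher drift in a diploid population of
effective size ``Ne``, the per-locus ancestry proportion ``p1`` is a
random variable with mean ``p0`` and (diffusion-limit) variance

    var(p1) = p0 (1 - p0) (1 - exp(-T / (2 Ne)))

and its distribution is well approximated by a Beta with those moments.
Observing ``K`` sampled haplotypes at a locus draws ``k ~ Binomial(K, p1)``,
so the observed fraction ``k/K`` follows a Beta-binomial compound whose
variance has the closed form

    var(k/K) = p0 (1 - p0) / K * (1 + (K - 1) rho),   rho = 1 - exp(-T/(2 Ne)).

Matching this to the empirical across-SNP variance of the observed
ancestry fraction yields a closed-form estimator of ``Ne`` given ``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DriftModel",
    "BetaMoments",
    "drift_variance",
    "wright_fisher_variance",
    "beta_moments",
    "model_observed_variance",
    "empirical_ancestry_variance",
    "estimate_ne",
    "estimate_ne_bisect",
    "simulate_unlinked_loci",
]


def _check_p0(p0: float) -> None:
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")


@dataclass(frozen=True)
class DriftModel:
    """Bundle of (p0, T, Ne, K) with the model's variance functions."""

    p0: float
    T: int
    Ne: float
    K: int

    def __post_init__(self) -> None:
        _check_p0(self.p0)
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.Ne <= 1:
            raise ValueError("Ne must be > 1")
        if self.K < 2:
            raise ValueError("K must be >= 2")

    @property
    def drift_variance(self) -> float:
        return drift_variance(self.p0, self.T, self.Ne)

    @property
    def observed_variance(self) -> float:
        return model_observed_variance(self.p0, self.T, self.Ne, self.K)


@dataclass(frozen=True)
class BetaMoments:
    """Beta(alpha, beta) shape parameters from a moment match."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def drift_variance(p0: float, T: float, Ne: float) -> float:
    """Variance of the ancestry proportion after T generations of drift.

    Uses the diffusion-limit factor ``1 - exp(-T/(2 Ne))``; see
    :func:`wright_fisher_variance` for the discrete-generation version
    (the two differ negligibly for T << Ne).
    """
    _check_p0(p0)
    if T < 0:
        raise ValueError("T must be >= 0")
    if Ne <= 1:
        raise ValueError("Ne must be > 1")
    return p0 * (1.0 - p0) * -math.expm1(-T / (2.0 * Ne))


def wright_fisher_variance(p0: float, T: int, Ne: float) -> float:
    """Exact discrete Wright-Fisher drift variance p0(1-p0)(1-(1-1/2Ne)^T)."""
    _check_p0(p0)
    return p0 * (1.0 - p0) * (1.0 - (1.0 - 1.0 / (2.0 * Ne)) ** T)


def beta_moments(p0: float, variance: float) -> BetaMoments:
    """Method-of-moments Beta shapes for mean ``p0`` and the given variance."""
    _check_p0(p0)
    vmax = p0 * (1.0 - p0)
    if not 0.0 < variance < vmax:
        raise ValueError(
            f"variance must lie in (0, p0(1-p0)) = (0, {vmax:.6g}); got {variance:.6g}")
    nu = vmax / variance - 1.0  # alpha + beta
    return BetaMoments(alpha=p0 * nu, beta=(1.0 - p0) * nu)


def model_observed_variance(p0: float, T: float, Ne: float, K: int) -> float:
    """Variance of the observed ancestry fraction k/K under drift + sampling.

    Closed form of the Beta-binomial compound:
    ``p0(1-p0)/K * (1 + (K-1) rho)`` with ``rho = 1 - exp(-T/(2 Ne))``;
    equivalently drift variance plus the binomial remainder
    ``(p0(1-p0) - var_drift)/K``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    _check_p0(p0)
    rho = -math.expm1(-T / (2.0 * Ne))
    return p0 * (1.0 - p0) / K * (1.0 + (K - 1) * rho)


def empirical_ancestry_variance(calls, target_label: str) -> tuple[float, float]:
    """Across-SNP variance and mean of the observed per-SNP ancestry fraction.

    Every SNP is used, linked or not, and the variance uses the population
    (1/M) denominator.  Returns ``(V_emp, p_bar)``.
    """
    from admixscan.scan import snp_mean_ancestry

    p_hat = snp_mean_ancestry(calls, target_label)
    if p_hat.size < 2:
        raise ValueError("need at least 2 SNPs to compute an across-SNP variance")
    return float(np.var(p_hat)), float(np.mean(p_hat))


def estimate_ne(V_emp: float, p0: float, T: float, K: int) -> float:
    """Effective population size matching the model variance to ``V_emp``.

    Closed-form inversion of :func:`model_observed_variance`:
    ``rho = (K V / (p0(1-p0)) - 1) / (K - 1)`` then ``Ne = -T / (2 ln(1-rho))``.

    Raises if ``V_emp`` is at or below the pure-sampling floor
    ``p0(1-p0)/K`` (no detectable drift, Ne unbounded) or at or above the
    fixation ceiling ``p0(1-p0)``.
    """
    _check_p0(p0)
    if K < 2:
        raise ValueError("K must be >= 2")
    vmax = p0 * (1.0 - p0)
    floor = vmax / K
    if V_emp <= floor:
        raise ValueError(
            f"no detectable drift: V_emp={V_emp:.6g} <= binomial sampling floor "
            f"{floor:.6g} (Ne -> infinity)")
    if V_emp >= vmax:
        raise ValueError(
            f"V_emp={V_emp:.6g} >= p0(1-p0)={vmax:.6g}: exceeds full-fixation variance")
    rho = (K * V_emp / vmax - 1.0) / (K - 1.0)
    return -T / (2.0 * math.log1p(-rho))


def estimate_ne_bisect(V_emp: float, p0: float, T: float, K: int,
                       lo: float = 1.0 + 1e-9, hi: float = 1e9) -> float:
    """Numeric root-finding fallback for :func:`estimate_ne` (cross-check)."""
    from scipy.optimize import brentq

    def f(ne: float) -> float:
        return model_observed_variance(p0, T, ne, K) - V_emp

    return float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))


def simulate_unlinked_loci(p0: float, T: int, Ne: int, K: int, n_loci: int,
                           rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Neutral Wright-Fisher drift at independent loci, then haplotype sampling.

    Each locus starts at frequency ``p0`` and drifts for ``T`` generations by
    binomial resampling of 2*Ne allele copies; the observed count is then
    ``k ~ Binomial(K, p_T)``.  Returns the observed fractions ``k/K`` as an
    array of length ``n_loci``.  This is the estimator's parameter-recovery
    testbed: loci are fully independent, so the only deviations from the
    analytic Beta-binomial model are Monte-Carlo noise and the discrete-vs-
    diffusion drift factor.
    """
    rng = np.random.default_rng(rng)
    if T < 0:
        raise ValueError("T must be >= 0")
    two_ne = 2 * int(Ne)
    p = np.full(n_loci, p0, dtype=np.float64)
    for _ in range(T):
        p = rng.binomial(two_ne, p) / two_ne
    k = rng.binomial(K, p)
    return k / K
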