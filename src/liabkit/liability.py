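"""Closed-form liability-threshold calculus.

Covers the observed<->liability scale conversion with case-control
ascertainment, recurrence risk in relatives via the bivariate-normal
orthant probability, the fraction of familial risk explained by a given
liability-scale heritability, and a log-normal relative-risk model for
polygenic score percentiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import integrate, optimize
from scipy.stats import norm

__all__ = [
    "LiabilityContext",
    "FamilialRiskInput",
    "PrsModel",
    "liability_context",
    "obs_to_liability",
    "liability_to_obs",
    "sensitivity_to_K",
    "recurrence_risk",
    "familial_fraction",
    "prs_top_fraction",
    "gamma_from_top_rr",
]


@dataclass(frozen=True)
class LiabilityContext:
    """Lifetime risk K, sample case fraction P, threshold geometry and the
    observed->liability conversion factor ``K^2 (1-K)^2 / (z^2 P (1-P))``."""

    K: float
    P: float
    t: float
    z: float
    factor: float


@dataclass(frozen=True)
class FamilialRiskInput:
    h2_l: float
    K: float
    a: float = 0.5  # relatedness coefficient; 0.5 = first degree
    lambda_obs: float = 2.45


@dataclass(frozen=True)
class PrsModel:
    """Log-normal relative-risk model: RR = exp(gamma * Z - gamma^2 / 2).

    The log-risk mean is fixed at ``-gamma^2/2`` so the population mean
    relative risk is exactly 1.
    """

    gamma: float
    K: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.K < 1:
            raise ValueError("K must be in (0, 1)")


def liability_context(K: float, P: float) -> LiabilityContext:
    """Build the ascertainment-corrected conversion context for lifetime risk
    ``K`` and sample case fraction ``P``."""
    if not 0 < K < 1:
        raise ValueError(f"K={K} outside (0, 1)")
    if not 0 < P < 1:
        raise ValueError(f"P={P} outside (0, 1)")
    t = norm.isf(K)
    z = norm.pdf(t)
    factor = (K * (1 - K)) ** 2 / (z**2 * P * (1 - P))
    return LiabilityContext(K=K, P=P, t=float(t), z=float(z), factor=float(factor))


def obs_to_liability(h2_obs: float, context: LiabilityContext, se: float | None = None):
    """Convert an observed-scale (0/1 phenotype) heritability to the liability
    scale; the SE scales by the same factor (delta method)."""
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    h2_l = h2_obs * context.factor
    if h2_l > 1:
        warnings.warn(f"liability-scale estimate {h2_l:.3f} exceeds 1", stacklevel=2)
    if se is None:
        return h2_l
    return h2_l, se * context.factor


def liability_to_obs(h2_l: float, context: LiabilityContext) -> float:
    return h2_l / context.factor


def sensitivity_to_K(h2_obs: float, P: float, K: float, delta: float) -> tuple[float, float]:
    """Range (min, max) of the liability-scale estimate over K - delta, K, K + delta."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    values = [
        obs_to_liability(h2_obs, liability_context(k, P))
        for k in (K - delta, K, K + delta)
    ]
    return min(values), max(values)


def bivariate_normal_orthant(t: float, r: float, tol: float = 1e-12) -> float:
    """P(X > t, Y > t) for standard bivariate normal with correlation r.

    Computed by adaptive quadrature of
    ``int_t^inf phi(x) * Phi_bar((t - r x) / sqrt(1 - r^2)) dx``.
    """
    if not -1 <= r <= 1:
        raise ValueError("correlation must be in [-1, 1]")
    K = norm.sf(t)
    if r >= 1 - 1e-12:
        return float(K)
    if abs(r) < 1e-14:
        return float(K * K)
    s = math.sqrt(1 - r * r)

    def integrand(x: float) -> float:
        return norm.pdf(x) * norm.sf((t - r * x) / s)

    val, err = integrate.quad(integrand, t, math.inf, epsabs=tol, epsrel=1e-12, limit=200)
    if err > max(1e-10, 1e-6 * max(val, 1e-300)):
        raise RuntimeError(f"orthant integration did not converge (err={err:g})")
    return float(val)


def recurrence_risk(h2_l: float, K: float, a: float = 0.5) -> float:
    """Relative risk in relatives of affected individuals,
    ``lambda = P(L2 > t | L1 > t) / K``, under the liability threshold model
    with liability correlation ``r = a * h2_l``."""
    if not 0 < K < 1:
        raise ValueError("K must be in (0, 1)")
    r = a * h2_l
    if not 0 <= r < 1 + 1e-12:
        raise ValueError(f"liability correlation a*h2_l = {r} outside [0, 1]")
    t = norm.isf(K)
    orthant = bivariate_normal_orthant(t, min(r, 1.0))
    return float(orthant / K**2)


def familial_fraction(h2_l: float, K: float, a: float, lambda_obs: float) -> float:
    """Fraction of the observed familial relative risk explained:
    ``ln(lambda_SNP) / ln(lambda_obs)``."""
    if lambda_obs <= 1:
        raise ValueError("lambda_obs must exceed 1")
    lam = recurrence_risk(h2_l, K, a)
    return float(math.log(lam) / math.log(lambda_obs))


def prs_top_fraction(model: PrsModel, q: float) -> tuple[float, float]:
    """(mean relative risk, absolute risk) for the top ``q`` of the polygenic
    risk distribution under the log-normal model.

    The mean relative risk in the top q is ``Phi(gamma - z_q) / q`` with
    ``z_q = Phi^{-1}(1 - q)``; absolute risk multiplies by K.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    z_q = norm.isf(q)
    rel = float(norm.cdf(model.gamma - z_q) / q)
    return rel, rel * model.K


def gamma_from_top_rr(target_rr: float, q: float, K: float) -> PrsModel:
    """Calibrate gamma so the top-``q`` mean relative risk equals ``target_rr``."""
    if target_rr < 1:
        raise ValueError("target relative risk must be >= 1")

    def gap(gamma: float) -> float:
        return prs_top_fraction(PrsModel(gamma=gamma, K=K), q)[0] - target_rr

    gamma = optimize.brentq(gap, 0.0, 20.0, xtol=1e-12)
    return PrsModel(gamma=float(gamma), K=K)
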