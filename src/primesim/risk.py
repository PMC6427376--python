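"""Risk mathematics: dose-response relative risks, mediation chains,
multiplicative combination, population-average risk, and potential impact
fractions.

Every function here is pure and deterministic. The central construction is
the population-average relative risk E[RR(X)] with X following a stratum's
intake distribution; contrasting that expectation between the baseline and
counterfactual scenarios yields the potential impact fraction (PIF)

    PIF = (E_base[RR] - E_cf[RR]) / E_base[RR],

which multiplied by observed cause-specific deaths gives deaths prevented
or delayed in one year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import integrate

from .domain import (
    IntakeDistribution,
    JShapeParameter,
    MediationParameter,
    Mediator,
    RelativeRiskParameter,
)
from .errors import ChainingError, NumericError

__all__ = [
    "RiskChange",
    "PopulationRisk",
    "relative_risk_at",
    "jshape_risk_at",
    "mediated_risk_at",
    "combine_risk_changes",
    "population_average_rr",
    "potential_impact_fraction",
    "deaths_averted",
]

#: Absolute quadrature tolerance for population expectations.
QUAD_ABS_TOL = 1e-8


@dataclass(frozen=True)
class RiskChange:
    """Proportional change in risk for one (exposure, cause) pathway.

    Positive values are risk reductions; a harmful shift yields a negative
    value. The value can never exceed 1 (a 100% risk reduction).
    """

    value: float
    source: str
    cause: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value > 1.0 + 1e-12:
            raise ValueError(f"risk change {self.value} exceeds 100% reduction")


@dataclass(frozen=True)
class PopulationRisk:
    """Expected relative risk over a stratum's intake distribution."""

    mean_rr: float
    cause: str
    scenario: str  # "baseline" or "counterfactual"

    def __post_init__(self) -> None:
        if not self.mean_rr > 0:
            raise ValueError(f"mean_rr must be > 0, got {self.mean_rr}")


def relative_risk_at(intake: float, param: RelativeRiskParameter) -> float:
    """Log-linear dose-response RR at one exposure level.

    RR(x) = exp(beta * (clamp(x) - reference)) with beta =
    ln(rr_per_increment) / increment; intake is clamped at ``cap_level``,
    the threshold above which no further change in risk accrues.
    """
    x = intake
    if param.cap_level is not None:
        x = min(x, param.cap_level)
    return math.exp(param.beta * (x - param.reference_level))


def jshape_risk_at(bmi: float, param: JShapeParameter) -> float:
    """J-shaped BMI risk curve: log-quadratic about the nadir.

    RR equals 1 exactly at the nadir and rises on both sides, with
    side-specific curvature.
    """
    if bmi <= 0:
        raise ValueError("bmi must be > 0")
    d = bmi - param.nadir
    curv = param.curvature_above if d >= 0 else param.curvature_below
    return math.exp(curv * d * d)


def mediated_risk_at(
    intake_change: float,
    med: MediationParameter,
    rr_per_mediator: RelativeRiskParameter,
) -> float:
    """RR change from an intake change acting through an intermediate factor.

    The mediator shifts by ``slope * intake_change``; the RR responds
    log-linearly on the mediator scale (reference = no change).
    """
    if rr_per_mediator.exposure != Mediator(med.mediator).value:
        raise ChainingError(
            f"mediation targets {Mediator(med.mediator).value!r} but the risk "
            f"parameter is on {rr_per_mediator.exposure!r}"
        )
    delta = med.slope * intake_change
    return math.exp(rr_per_mediator.beta * delta)


def combine_risk_changes(changes: Iterable[RiskChange]) -> RiskChange:
    """Multiplicative combination of risk changes for one cause.

    Survival fractions multiply: combined = 1 - prod(1 - v_i). The joint
    benefit of several simultaneous changes is therefore less than the sum
    of its parts and can never exceed a 100% reduction.
    """
    changes = list(changes)
    if not changes:
        return RiskChange(0.0, source="combined", cause=None)
    causes = {c.cause for c in changes if c.cause is not None}
    if len(causes) > 1:
        raise ValueError(f"cannot combine risk changes across causes {causes}")
    surviving = 1.0
    for c in changes:
        surviving *= 1.0 - c.value
    return RiskChange(
        1.0 - surviving, source="combined", cause=next(iter(causes), None)
    )


def _gauss_legendre_expectation(
    dist: IntakeDistribution, param: RelativeRiskParameter, npoints: int = 64
) -> float:
    """64-point Gauss-Legendre fallback on a mean +/- 8 SD window."""
    frozen = dist.frozen()
    lo_support, hi_support = frozen.support()
    lo = max(lo_support, dist.mean - 8.0 * dist.sd)
    hi = min(hi_support, dist.mean + 8.0 * dist.sd)
    nodes, weights = np.polynomial.legendre.leggauss(npoints)
    x = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    if param.cap_level is not None:
        x_eff = np.minimum(x, param.cap_level)
    else:
        x_eff = x
    vals = np.exp(param.beta * (x_eff - param.reference_level)) * frozen.pdf(x)
    return float(0.5 * (hi - lo) * np.dot(weights, vals))


def _scalar_pdf(dist: IntakeDistribution):
    """Fast scalar pdf for the quadrature integrand.

    Equivalent to ``dist.frozen().pdf`` but without per-call distribution
    machinery, which dominates adaptive-quadrature cost.
    """
    from .domain import DistributionFamily, gamma_params, lognormal_params

    if dist.family is DistributionFamily.NORMAL:
        mu, sd = dist.mean, dist.sd
        c = 1.0 / (sd * math.sqrt(2.0 * math.pi))

        def pdf(x: float) -> float:
            z = (x - mu) / sd
            return c * math.exp(-0.5 * z * z)

    elif dist.family is DistributionFamily.LOGNORMAL:
        mu, sigma = lognormal_params(dist.mean, dist.sd)

        def pdf(x: float) -> float:
            if x <= 0.0:
                return 0.0
            z = (math.log(x) - mu) / sigma
            return math.exp(-0.5 * z * z) / (x * sigma * math.sqrt(2.0 * math.pi))

    else:
        k, theta = gamma_params(dist.mean, dist.sd)
        logc = -math.lgamma(k) - k * math.log(theta)

        def pdf(x: float) -> float:
            if x <= 0.0:
                return 0.0
            return math.exp(logc + (k - 1.0) * math.log(x) - x / theta)

    return pdf


@lru_cache(maxsize=16384)
def _expected_rr(dist: IntakeDistribution, param: RelativeRiskParameter) -> float:
    """E[RR(X)] by adaptive quadrature, with the cap handled analytically.

    For a capped parameter the expectation splits into an integral below the
    cap plus RR(cap) times the survival mass at the cap, which keeps the
    integrand smooth. Falls back to fixed Gauss-Legendre when the adaptive
    rule struggles.
    """
    frozen = dist.frozen()
    beta = param.beta
    ref = param.reference_level
    lo, hi = frozen.support()
    # Restrict to a +/- 12 SD window: the truncated mass is negligible
    # (< 1e-30) and the adaptive rule cannot miss a distribution that is
    # narrow relative to an infinite integration domain.
    lo = max(lo, dist.mean - 12.0 * dist.sd)
    hi = min(hi, dist.mean + 12.0 * dist.sd)
    pdf = _scalar_pdf(dist)

    def integrand(x):
        return math.exp(beta * (x - ref)) * pdf(x)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            if param.cap_level is not None:
                cap = param.cap_level
                if cap <= lo:
                    return math.exp(beta * (cap - ref))
                upper = min(cap, hi)
                val, _ = integrate.quad(
                    integrand, lo, upper, epsabs=QUAD_ABS_TOL, limit=200
                )
                val += math.exp(beta * (cap - ref)) * float(frozen.sf(cap))
            else:
                val, _ = integrate.quad(
                    integrand, lo, hi, epsabs=QUAD_ABS_TOL, limit=200
                )
    except integrate.IntegrationWarning:
        val = _gauss_legendre_expectation(dist, param)
    if not math.isfinite(val) or val <= 0:
        raise NumericError(
            f"expectation of RR did not converge for exposure "
            f"{param.exposure!r} (family={dist.family.value}, mean={dist.mean}, "
            f"sd={dist.sd}, beta={beta:.6g}): got {val}"
        )
    return val


def population_average_rr(
    dist: IntakeDistribution,
    param: RelativeRiskParameter,
    scenario: str = "baseline",
) -> PopulationRisk:
    """Population-average relative risk E[RR(X)] with X ~ ``dist``.

    The expectation is taken over individuals, not evaluated at the mean
    intake: for a log-linear RR this matters whenever the within-population
    variance is nonzero, which is exactly why the counterfactual shift
    preserves that variance.
    """
    value = _expected_rr(dist, param)
    return PopulationRisk(mean_rr=value, cause=param.cause, scenario=scenario)


def potential_impact_fraction(
    baseline: PopulationRisk, counterfactual: PopulationRisk
) -> float:
    """Proportional mortality reduction when the exposure distribution moves
    from baseline to counterfactual: (E_b - E_c) / E_b. Always <= 1."""
    if baseline.cause != counterfactual.cause:
        raise ValueError(
            f"PIF requires matching causes, got {baseline.cause!r} vs "
            f"{counterfactual.cause!r}"
        )
    if baseline.scenario == counterfactual.scenario:
        raise ValueError("PIF needs one baseline and one counterfactual risk")
    return (baseline.mean_rr - counterfactual.mean_rr) / baseline.mean_rr


def deaths_averted(pif: float, deaths: float) -> float:
    """Deaths prevented or delayed in one year: PIF x observed deaths.

    Bounded above by ``deaths`` because the PIF can never exceed 1; a
    harmful shift (negative PIF) yields a negative value, i.e. excess
    deaths.
    """
    if pif > 1.0 + 1e-12:
        raise ValueError(f"pif {pif} exceeds 1")
    if deaths < 0:
        raise ValueError("deaths must be >= 0")
    return pif * deaths


def clear_expectation_cache() -> None:
    """Drop memoised population expectations (used between large runs)."""
    _expected_rr.cache_clear()
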