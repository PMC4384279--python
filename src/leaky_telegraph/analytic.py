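"""Closed-form stationary distribution and moments of the leaky model.

The stationary gene-product law of the two-state auto-regulatory model
with leakage is a finite binomial mixture of confluent hypergeometric
terms,

    P(n) = (g*A/n!) * sum_{m=0}^{n} C(n,m) * lambda0^(n-m)
           * [(f+1)*Q]^m * (alpha-1)_m/(beta-1)_m
           * 1F1(alpha+m-1, beta+m-1; -Q),

with the constants of :func:`leaky_telegraph.params.derived_constants`
and (c)_m the Pochhammer symbol.  Means and variances come from the
probability generating function G(z):

    <n>      = G'(1)
    sigma^2  = G''(1) + G'(1) - G'(1)^2
    eta_n^2  = sigma^2 / <n>^2        (noise intensity, squared CV)

Terms of the series span hundreds of orders of magnitude (lambda0^(n-m)
with lambda0 up to ~40 and n up to a few hundred), so the sum is
accumulated in log space with sign tracking.

For the positive-feedback labeling (lambda1 < lambda0, i.e. lam < 0)
the domain of validity of the closed form is not established; there the
result is validated point-by-point against the truncated-CME solver and
silently replaced by it when they disagree, with the event logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .errors import DegenerateParameterError, DomainError, NumericalError
from .params import GeneModelParams, derived_constants, normalize
from .special import hyp1f1_stable, log_hyp1f1

__all__ = [
    "DiscretePMF",
    "MomentSummary",
    "stationary_pmf",
    "generating_derivatives",
    "moments",
]

logger = logging.getLogger(__name__)

#: TV threshold for accepting the analytic law in the lam < 0 regime.
_FALLBACK_TV = 1e-6
#: Relative size of a negative probability treated as a real failure.
_NEG_PROB_TOL = 1e-10


@dataclass(frozen=True)
class DiscretePMF:
    """Stationary gene-product distribution on the support 0..N."""

    probs: np.ndarray
    source: str = "analytic"
    params: GeneModelParams | None = field(default=None, compare=False)
    renorm_residual: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))

    @property
    def support_max(self) -> int:
        return len(self.probs) - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))


@dataclass(frozen=True)
class MomentSummary:
    """Mean, variance and noise intensity of the product copy number."""

    mean: float
    variance: float
    noise: float
    gprime: float
    gdoubleprime: float


def _is_constitutive(p: GeneModelParams) -> bool:
    return p.f == 0.0 and p.lambda1 == p.lambda0


def _poisson_pmf(p: GeneModelParams, n_max: int | str) -> DiscretePMF:
    rate = p.lambda0
    if n_max == "auto":
        n_max = max(50, math.ceil(rate + 10.0 * math.sqrt(max(rate, 1.0))))
    probs = poisson.pmf(np.arange(int(n_max) + 1), rate)
    residual = 1.0 - probs.sum()
    return DiscretePMF(
        probs=probs / probs.sum(),
        source="poisson",
        params=p,
        renorm_residual=residual,
    )


def _auto_n_max(p: GeneModelParams) -> int:
    """Truncation capturing essentially all stationary mass.

    mean + 10*sigma (floor 50) from the generating-function moments;
    falls back to CME-oracle moments when the analytic path is refused.
    """
    try:
        m = moments(p, _validate=False)
        mean, var = m.mean, m.variance
    except (DegenerateParameterError, NumericalError, DomainError):
        from .cme import steady_state

        marg = steady_state(p).marginal().probs
        n = np.arange(len(marg))
        mean = float(n @ marg)
        var = float((n - mean) ** 2 @ marg)
    if not (math.isfinite(mean) and math.isfinite(var)) or var < 0:
        var = max(mean, 1.0)
    return max(50, math.ceil(mean + 10.0 * math.sqrt(max(var, 1.0))))


def _analytic_log_pmf(p: GeneModelParams, n_max: int) -> np.ndarray:
    """Signed log-space evaluation of the closed-form P(n), unnormalized
    only by floating-point error (the analytic prefactor is included)."""
    dc = derived_constants(p)
    fp1 = p.f + 1.0
    w = fp1 * dc.Q  # the [(f+1)Q]^m base; equals R/(f+1)
    mgrid = np.arange(n_max + 1)

    # 1F1(alpha+m-1, beta+m-1; -Q) for every m, arbitrary precision.
    logF = np.empty(n_max + 1)
    signF = np.empty(n_max + 1)
    for m in range(n_max + 1):
        logF[m], signF[m] = log_hyp1f1(dc.alpha + m - 1.0, dc.beta + m - 1.0, -dc.Q)

    # Pochhammer ratios (alpha-1)_m / (beta-1)_m, iteratively with signs.
    logpoch = np.zeros(n_max + 1)
    signpoch = np.ones(n_max + 1)
    la, sa = 0.0, 1.0
    for m in range(1, n_max + 1):
        num = dc.alpha - 2.0 + m
        den = dc.beta - 2.0 + m
        if num == 0.0 or den == 0.0:
            # Pochhammer hits zero: every later numerator term vanishes
            # (or the ratio is singular) -- flag via -inf / error.
            if den == 0.0:
                raise NumericalError(
                    f"(beta-1)_{m} = 0: beta-1 is a non-positive integer"
                )
            la, sa = float("-inf"), 0.0
        else:
            la += math.log(abs(num)) - math.log(abs(den))
            sa *= math.copysign(1.0, num) * math.copysign(1.0, den)
        logpoch[m], signpoch[m] = la, sa

    log_w = math.log(abs(w)) if w != 0.0 else float("-inf")
    if w < 0:
        sign_w_m = np.where(mgrid % 2 == 0, 1.0, -1.0)
    else:
        sign_w_m = np.ones(n_max + 1)

    base_m = mgrid * log_w + logpoch + logF
    sign_m = sign_w_m * signpoch * signF

    log_lam0 = math.log(p.lambda0) if p.lambda0 > 0.0 else float("-inf")

    # Prefactor g*A = exp(-lambda0) / 1F1(alpha-1, beta-1; f*Q).
    logFA, signFA = log_hyp1f1(dc.alpha - 1.0, dc.beta - 1.0, p.f * dc.Q)
    log_gA = -p.lambda0 - logFA

    logP = np.full(n_max + 1, float("-inf"))
    signP = np.zeros(n_max + 1)
    gl = gammaln(np.arange(n_max + 2) + 1.0)  # gl[k] = log k!
    for n in range(n_max + 1):
        m = mgrid[: n + 1]
        with np.errstate(invalid="ignore"):
            lt = (
                gl[n]
                - gl[m]
                - gl[n - m]
                + (n - m) * log_lam0
                + base_m[: n + 1]
            )
        if p.lambda0 == 0.0:
            lt = np.where(m == n, gl[n] - gl[m] - gl[n - m] + base_m[: n + 1],
                          float("-inf"))
        total, sgn = logsumexp(lt, b=sign_m[: n + 1], return_sign=True)
        logP[n] = log_gA - gl[n] + total
        signP[n] = sgn * signFA
    return signP * np.exp(logP)


def _finalize_pmf(raw: np.ndarray, p: GeneModelParams, source: str) -> DiscretePMF:
    peak = np.nanmax(raw) if np.isfinite(raw).any() else float("nan")
    if not math.isfinite(peak) or peak <= 0:
        raise NumericalError(
            "analytic series produced no finite positive mass; "
            "fall back to leaky_telegraph.cme.steady_state"
        )
    worst_neg = raw.min()
    if worst_neg < -_NEG_PROB_TOL * peak:
        raise NumericalError(
            f"negative probability {worst_neg:.3e} beyond tolerance; "
            "fall back to leaky_telegraph.cme.steady_state"
        )
    probs = np.clip(raw, 0.0, None)
    residual = 1.0 - probs.sum()
    if abs(residual) > 1e-9:
        logger.info("pmf renormalization residual %.3e", residual)
    return DiscretePMF(
        probs=probs / probs.sum(),
        source=source,
        params=p,
        renorm_residual=residual,
    )


def _tv(a: np.ndarray, b: np.ndarray) -> float:
    n = max(len(a), len(b))
    pa = np.zeros(n)
    pb = np.zeros(n)
    pa[: len(a)] = a
    pb[: len(b)] = b
    return 0.5 * float(np.abs(pa - pb).sum())


def stationary_pmf(params: GeneModelParams, n_max: int | str = "auto") -> DiscretePMF:
    """Stationary distribution of the product copy number.

    Routes through (in order): the Poisson closed form in the
    constitutive limit (lambda1 == lambda0, f == 0); the confluent
    hypergeometric closed form; and, in the lam < 0 regime or on
    numerical failure of the series, the truncated-CME solver.

    Raises
    ------
    DegenerateParameterError
        If the analytic constants are singular (|R| ~ 0) -- call
        :func:`leaky_telegraph.cme.steady_state` directly in that case.
    """
    p = normalize(params)
    if _is_constitutive(p):
        return _poisson_pmf(p, n_max)
    dc = derived_constants(p)  # raises DegenerateParameterError when singular
    if n_max == "auto":
        n_max = _auto_n_max(p)
    n_max = int(n_max)

    from .cme import steady_state

    if dc.lam < 0:
        # Positive-feedback labeling: the closed form is used only if it
        # reproduces the oracle; otherwise the oracle is authoritative.
        oracle = steady_state(p, n_max=n_max).marginal()
        try:
            raw = _analytic_log_pmf(p, n_max)
            cand = _finalize_pmf(raw, p, "analytic")
        except NumericalError:
            logger.info("analytic series failed for lam < 0; using CME result")
            return DiscretePMF(
                probs=oracle.probs, source="cme-fallback", params=p
            )
        if _tv(cand.probs, oracle.probs) > _FALLBACK_TV:
            logger.info(
                "analytic pmf disagrees with CME oracle (lam < 0); using CME result"
            )
            return DiscretePMF(probs=oracle.probs, source="cme-fallback", params=p)
        return cand

    raw = _analytic_log_pmf(p, n_max)
    return _finalize_pmf(raw, p, "analytic")


def generating_derivatives(params: GeneModelParams) -> tuple[float, float]:
    """First and second derivatives G'(1), G''(1) of the generating
    function at z = 1 (factorial moments of the stationary law)."""
    p = normalize(params)
    dc = derived_constants(p)
    fQ = p.f * dc.Q
    F1 = hyp1f1_stable(dc.alpha - 1.0, dc.beta - 1.0, fQ)
    F2 = hyp1f1_stable(dc.alpha, dc.beta, fQ)
    F3 = hyp1f1_stable(dc.alpha + 1.0, dc.beta + 1.0, fQ)
    gF1 = dc.g * F1
    if gF1 == 0.0:
        raise DegenerateParameterError("g * 1F1(alpha-1, beta-1; fQ) = 0")
    gprime = p.lambda0 + dc.lam * F2 / gF1
    denom = dc.lam + p.gamma1 + p.gamma0 + p.f + 1.0 - dc.R / (1.0 + p.f)
    if abs(denom) < 1e-12 * max(1.0, abs(dc.lam)):
        raise DegenerateParameterError(
            "vanishing denominator in the second factorial moment"
        )
    gdouble = (
        dc.g * p.lambda0**2 * F1
        + 2.0 * dc.lam * p.lambda0 * F2
        + dc.lam * (dc.lam * p.gamma1 + dc.R) / denom * F3
    ) / gF1
    return float(gprime), float(gdouble)


def moments(params: GeneModelParams, _validate: bool = True) -> MomentSummary:
    """Stationary mean, variance and noise intensity eta^2 = var/mean^2.

    Raises
    ------
    DomainError
        If the mean is zero (noise intensity undefined).
    """
    p = normalize(params)
    if _is_constitutive(p):
        rate = p.lambda0
        if rate == 0.0:
            raise DomainError("mean expression is zero; noise undefined")
        return MomentSummary(
            mean=rate, variance=rate, noise=1.0 / rate, gprime=rate,
            gdoubleprime=rate**2,
        )
    gp, gpp = generating_derivatives(p)
    mean = gp
    variance = gpp + gp - gp * gp
    if mean <= 0.0:
        raise DomainError("mean expression is zero; noise undefined")
    if variance < 0.0:
        if variance > -1e-9 * max(mean * mean, 1.0):
            variance = 0.0
        else:
            raise NumericalError(
                f"negative variance {variance:.3e} from the generating-function "
                "moments"
            )
    return MomentSummary(
        mean=mean, variance=variance, noise=variance / mean**2,
        gprime=gp, gdoubleprime=gpp,
    )
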