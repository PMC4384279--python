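"""Kinetic parameters of the leaky two-state auto-regulatory gene model.

The reaction network has a promoter with two activity states D0 and D1 and
a single gene-product species P::

    D0 --gamma1--> D1          D1 --gamma0--> D0      D1 + P --f--> D0 + P
    D1 --lambda1--> D1 + P     D0 --lambda0--> D0 + P     P --d--> 0

The product acts catalytically on the D1 -> D0 transition (it is not
consumed), so the per-state switching propensities are ``gamma1`` out of
D0 and ``gamma0 + f*n`` out of D1, with ``n`` the current copy number.

Which state is "ON" depends on the synthesis rates: if ``lambda1 >>
lambda0`` then D1 is the active state, ``lambda0`` is the leakage rate
and the feedback is negative (the product promotes switching OFF);
if ``lambda0 >> lambda1`` the roles are mirrored and the feedback is
positive.

All analytic results assume rates normalized by the degradation rate
``d`` (time measured in units of the product lifetime).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import (
    ConfigurationError,
    DegenerateParameterError,
    InvalidParameterError,
)

__all__ = [
    "GeneModelParams",
    "DerivedConstants",
    "normalize",
    "feedback_labeling",
    "derived_constants",
    "params_from_config",
    "R_RELATIVE_TOLERANCE",
]

#: Relative tolerance below which |R| is treated as zero and the analytic
#: path refused (alpha = 1 + lambda*gamma1/R diverges as R -> 0).
R_RELATIVE_TOLERANCE = 1e-10

_PARAM_KEYS = ("gamma1", "gamma0", "f", "lambda1", "lambda0", "d")


@dataclass(frozen=True)
class GeneModelParams:
    """The six kinetic rates of the reaction network.

    Parameters
    ----------
    gamma1
        Promoter transition rate D0 -> D1 (per unit time).
    gamma0
        Spontaneous promoter transition rate D1 -> D0 (per unit time).
    f
        Feedback strength: per-molecule contribution of the product to
        the D1 -> D0 propensity (per unit time per molecule).
    lambda1
        Product synthesis rate while the promoter is in D1.
    lambda0
        Product synthesis rate while the promoter is in D0.
    d
        Product degradation rate (per unit time).  Defaults to 1, i.e.
        rates already normalized by the product lifetime.
    """

    gamma1: float
    gamma0: float
    f: float
    lambda1: float
    lambda0: float
    d: float = 1.0

    def __post_init__(self) -> None:
        for key in _PARAM_KEYS:
            value = getattr(self, key)
            if not math.isfinite(value):
                raise InvalidParameterError(f"{key} must be finite, got {value!r}")
            if value < 0:
                raise InvalidParameterError(f"{key} must be >= 0, got {value!r}")
        if self.d <= 0:
            raise InvalidParameterError(f"d must be > 0, got {self.d!r}")

    def replace(self, **changes: float) -> "GeneModelParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {key: float(getattr(self, key)) for key in _PARAM_KEYS}

    def config_hash(self) -> str:
        """Short stable hash of the parameter set, for output headers."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def normalize(params: GeneModelParams) -> GeneModelParams:
    """Divide all rates by the degradation rate; the result has d = 1.

    Idempotent, and leaves every dimensionless ratio (e.g. lambda1/gamma0)
    unchanged.
    """
    if params.d == 1.0:
        return params
    d = params.d
    return GeneModelParams(
        gamma1=params.gamma1 / d,
        gamma0=params.gamma0 / d,
        f=params.f / d,
        lambda1=params.lambda1 / d,
        lambda0=params.lambda0 / d,
        d=1.0,
    )


def feedback_labeling(params: GeneModelParams) -> str:
    """Classify the regulation implied by the synthesis rates.

    Returns ``"negative"`` when lambda1 > lambda0 (D1 is ON, lambda0 is
    the leakage rate), ``"positive"`` when lambda0 > lambda1 (D0 is ON,
    lambda1 is the leakage rate) and ``"constitutive"`` on a tie.
    """
    if params.lambda1 > params.lambda0:
        return "negative"
    if params.lambda0 > params.lambda1:
        return "positive"
    return "constitutive"


@dataclass(frozen=True)
class DerivedConstants:
    """Constants of the closed-form stationary distribution.

    With rates normalized by ``d``::

        lam   = lambda1 - lambda0
        R     = lam - f*lambda0
        Q     = R / (f+1)^2
        g     = (lam + gamma1 + gamma0)/gamma1 - R/(gamma1*(f+1))
        alpha = 1 + lam*gamma1/R
        beta  = 1 + (lam + gamma0 + gamma1)/(f+1) - R/(f+1)^2
        A     = exp(-lambda0) / (g * 1F1(alpha-1, beta-1; f*Q))

    ``A`` is the normalization prefactor; the stationary probability of
    ``n`` molecules is a binomial mixture of Kummer 1F1 terms weighted
    by ``g*A/n!``.
    """

    lam: float
    R: float
    Q: float
    g: float
    alpha: float
    beta: float
    A: float


def derived_constants(params: GeneModelParams) -> DerivedConstants:
    """Compute the seven constants of the analytic stationary solution.

    Raises
    ------
    DegenerateParameterError
        When ``|R| <= R_RELATIVE_TOLERANCE * max(lambda1, lambda0, 1)``;
        alpha diverges there and callers must use the CME solver.
    """
    p = normalize(params)
    lam = p.lambda1 - p.lambda0
    R = lam - p.f * p.lambda0
    tol = R_RELATIVE_TOLERANCE * max(p.lambda1, p.lambda0, 1.0)
    if abs(R) <= tol:
        raise DegenerateParameterError(
            f"|R| = {abs(R):.3e} <= {tol:.3e}: the analytic solution is "
            "singular here; use leaky_telegraph.cme.steady_state instead"
        )
    if p.gamma1 == 0:
        raise DegenerateParameterError(
            "gamma1 = 0: g and alpha are undefined; use the CME solver"
        )
    fp1 = p.f + 1.0
    Q = R / fp1**2
    g = (lam + p.gamma1 + p.gamma0) / p.gamma1 - R / (p.gamma1 * fp1)
    alpha = 1.0 + lam * p.gamma1 / R
    beta = 1.0 + (lam + p.gamma0 + p.gamma1) / fp1 - R / fp1**2

    from .special import hyp1f1_stable  # local import: avoids cycle at import time

    denom = g * hyp1f1_stable(alpha - 1.0, beta - 1.0, p.f * Q)
    if denom == 0 or not math.isfinite(denom):
        raise DegenerateParameterError(
            "normalization prefactor A is not finite for this parameter set"
        )
    A = math.exp(-p.lambda0) / denom
    return DerivedConstants(lam=lam, R=R, Q=Q, g=g, alpha=alpha, beta=beta, A=A)


def params_from_config(source: str | Path | dict) -> GeneModelParams:
    """Read a parameter set from a flat YAML/JSON mapping or a dict.

    Recognized keys: gamma1, gamma0, f, lambda1, lambda0, d (d optional,
    default 1).  Unknown keys raise :class:`ConfigurationError`.
    """
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text()
        import yaml

        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {source} is not a flat mapping")
    unknown = set(data) - set(_PARAM_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    missing = set(_PARAM_KEYS[:-1]) - set(data)
    if missing:
        raise ConfigurationError(f"missing config keys: {sorted(missing)}")
    return GeneModelParams(**{k: float(v) for k, v in data.items()})
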