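"""Scan drivers: noise vs. leakage, modality vs. leakage, burst scans.

The central numerical experiment of the model is to raise the promoter
leakage rate -- ``lambda0`` in the negative-feedback labeling,
``lambda1`` in the positive one -- and track what happens to the noise
intensity, the number of peaks of the stationary law, and the bursting
kinetics.  The noise scan comes in two flavors: *free mean*, where the
leakage is simply swept, and *fixed mean*, where a compensating
parameter (gamma1 down, gamma0 up, f up, or the main synthesis rate
down) is re-solved at each grid point so the mean expression stays at
its zero-leakage value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analytic import moments, stationary_pmf
from .bursts import empirical_burst
from .cme import steady_state
from .diststats import count_modes, pmf_moments
from .errors import (
    ConfigurationError,
    InfeasiblePointError,
    InsufficientDataError,
    LeakyTelegraphError,
)
from .params import GeneModelParams, feedback_labeling, normalize
from .ssa import simulate

__all__ = [
    "CompensationMode",
    "solve_compensation",
    "noise_vs_leakage_scan",
    "modality_scan",
    "burst_scan",
]

logger = logging.getLogger(__name__)

_TARGETS = ("gamma1_down", "gamma0_up", "f_up", "lambda1_down")
_MEAN_RTOL = 1e-8
#: Fraction of analytic scan rows re-verified against the CME oracle.
_AUDIT_EVERY = 10


@dataclass(frozen=True)
class CompensationMode:
    """How the mean expression is held fixed while leakage rises.

    ``target`` names the compensating parameter and its direction;
    ``lambda1_down`` means the majority synthesis rate (lambda0 in the
    positive-feedback labeling) is lowered.
    """

    target: str
    fixed_mean: float

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ConfigurationError(
                f"unknown compensation target {self.target!r}; one of {_TARGETS}"
            )
        if self.fixed_mean <= 0:
            raise ConfigurationError("fixed_mean must be > 0")


def _leakage_field(params: GeneModelParams) -> str:
    # The leakage rate is the minority synthesis rate.
    return "lambda0" if feedback_labeling(params) != "positive" else "lambda1"


def _with_leakage(params: GeneModelParams, leakage: float) -> GeneModelParams:
    return params.replace(**{_leakage_field(params): float(leakage)})


def _majority_field(params: GeneModelParams) -> str:
    return "lambda1" if _leakage_field(params) == "lambda0" else "lambda0"


def solve_compensation(
    base: GeneModelParams, leakage: float, mode: CompensationMode
) -> GeneModelParams:
    """Parameter set with the given leakage and the mean re-fixed.

    Sets the leakage rate and adjusts the compensating parameter named
    by ``mode.target`` so the stationary mean equals ``mode.fixed_mean``
    to 1e-8 relative, by safeguarded bracketed root finding.

    Raises
    ------
    InfeasiblePointError
        When no nonnegative value of the compensating parameter
        attains the target mean at this leakage.
    """
    base = normalize(base)
    leaked = _with_leakage(base, leakage)
    field = {
        "gamma1_down": "gamma1",
        "gamma0_up": "gamma0",
        "f_up": "f",
        "lambda1_down": _majority_field(base),
    }[mode.target]

    def mean_err(value: float) -> float:
        point = leaked.replace(**{field: value})
        try:
            mean = moments(point).mean
        except LeakyTelegraphError:
            # Degenerate analytic constants (R ~ 0) or zero mean along
            # the bracket: the oracle mean is always defined.
            probs = steady_state(point).marginal().probs
            mean = float(np.arange(len(probs)) @ probs)
        return mean - mode.fixed_mean

    x0 = getattr(base, field)
    # The mean is monotone in each compensating parameter: increasing in
    # gamma1 and the majority synthesis rate, decreasing in gamma0 and f.
    if mode.target in ("gamma1_down", "lambda1_down"):
        lo, hi = 1e-12, max(x0, 1e-6)
        for _ in range(80):
            if mean_err(hi) >= 0:
                break
            hi *= 2.0
        else:
            raise InfeasiblePointError(f"no bracket for {field} at leakage {leakage}")
        if mean_err(lo) > 0:
            raise InfeasiblePointError(
                f"mean exceeds target even at {field} -> 0 (leakage {leakage})"
            )
    else:
        lo, hi = 0.0, max(x0, 1e-6)
        if mean_err(lo) < 0:
            raise InfeasiblePointError(
                f"mean below target even at {field} = 0 (leakage {leakage})"
            )
        for _ in range(80):
            if mean_err(hi) <= 0:
                break
            hi *= 2.0
        else:
            raise InfeasiblePointError(f"no bracket for {field} at leakage {leakage}")
    root = brentq(mean_err, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    solved = leaked.replace(**{field: float(root)})
    achieved = moments(solved).mean
    if abs(achieved - mode.fixed_mean) > _MEAN_RTOL * mode.fixed_mean:
        raise InfeasiblePointError(
            f"root finder left mean at {achieved!r} (target {mode.fixed_mean!r})"
        )
    return solved


def _point_stats(params: GeneModelParams) -> tuple[float, float, float, str]:
    """(mean, variance, noise, path) with an oracle route for safety."""
    try:
        m = moments(params)
        return m.mean, m.variance, m.noise, "analytic"
    except LeakyTelegraphError:
        m = pmf_moments(steady_state(params).marginal())
        return m.mean, m.variance, m.noise, "cme"


def noise_vs_leakage_scan(
    base: GeneModelParams,
    leakage_grid: np.ndarray,
    mode: CompensationMode | None = None,
    audit: bool = True,
) -> pd.DataFrame:
    """Noise intensity along a leakage grid, free or fixed mean.

    Returns one row per grid point: (leakage, compensating value or
    NaN, mean, variance, noise, path).  Infeasible fixed-mean points
    are recorded as gaps (NaN row) rather than aborting the scan.
    Every ``_AUDIT_EVERY``-th analytic row is re-verified against the
    CME oracle at 1e-6 relative tolerance.
    """
    grid = np.asarray(leakage_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ConfigurationError("leakage grid must be nonempty and increasing")
    rows = []
    for i, leak in enumerate(grid):
        comp_value = np.nan
        try:
            if mode is None:
                point = _with_leakage(normalize(base), leak)
            else:
                point = solve_compensation(base, leak, mode)
                field = {
                    "gamma1_down": "gamma1",
                    "gamma0_up": "gamma0",
                    "f_up": "f",
                    "lambda1_down": _majority_field(base),
                }[mode.target]
                comp_value = getattr(point, field)
            mean, var, noise, path = _point_stats(point)
        except InfeasiblePointError as err:
            logger.warning("infeasible point at leakage %g: %s", leak, err)
            rows.append((leak, np.nan, np.nan, np.nan, np.nan, "infeasible"))
            continue
        if audit and path == "analytic" and i % _AUDIT_EVERY == 0:
            m_o = pmf_moments(steady_state(point).marginal())
            rel = abs(noise - m_o.noise) / max(m_o.noise, 1e-300)
            if rel > 1e-6:
                raise LeakyTelegraphError(
                    f"audit failure at leakage {leak}: analytic noise off by {rel:.2e}"
                )
            logger.debug("audit ok at leakage %g (rel %.2e)", leak, rel)
        rows.append((leak, comp_value, mean, var, noise, path))
    return pd.DataFrame(
        rows,
        columns=["leakage", "compensating_value", "mean", "variance", "noise",
                 "path"],
    )


def modality_scan(
    base: GeneModelParams, leakage_grid: np.ndarray
) -> pd.DataFrame:
    """Peak count of the stationary law along a leakage grid."""
    grid = np.asarray(leakage_grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("leakage grid must be nonempty")
    rows = []
    for leak in grid:
        point = _with_leakage(normalize(base), leak)
        pmf = stationary_pmf(point)
        report = count_modes(pmf)
        rows.append(
            (leak, report.n_modes, list(report.mode_locations), pmf.source)
        )
    return pd.DataFrame(rows, columns=["leakage", "n_modes", "mode_locations",
                                       "path"])


def burst_scan(
    base: GeneModelParams,
    leakage_grid: np.ndarray,
    seeds: tuple[int, ...] = tuple(range(8)),
    t_end: float = 2e4,
    mode: CompensationMode | None = None,
) -> pd.DataFrame:
    """Empirical burst statistics along a leakage grid.

    Per grid point, burst frequency/size and dwell times are averaged
    over independent simulation seeds; columns ``bf_se``/``bs_se``
    carry standard errors across seeds.  Points with insufficient data
    are flagged, not fatal.
    """
    grid = np.asarray(leakage_grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("leakage grid must be nonempty")
    rows = []
    for leak in grid:
        try:
            point = (
                _with_leakage(normalize(base), leak)
                if mode is None
                else solve_compensation(base, leak, mode)
            )
        except InfeasiblePointError:
            rows.append((leak, *[np.nan] * 8, 0, "infeasible"))
            continue
        bfs, bss, tons, toffs, counts = [], [], [], [], []
        for seed in seeds:
            try:
                summary = empirical_burst(simulate(point, t_end=t_end, seed=seed))
            except InsufficientDataError as err:
                logger.warning("seed %d at leakage %g: %s", seed, leak, err)
                continue
            bfs.append(summary.mean_bf)
            bss.append(summary.mean_bs)
            tons.append(summary.tau_on)
            toffs.append(summary.tau_off)
            counts.append(summary.n_bursts)
        if len(bfs) < 2:
            rows.append((leak, *[np.nan] * 8, 0, "insufficient"))
            continue
        k = len(bfs)
        rows.append((
            leak,
            float(np.mean(bfs)), float(np.std(bfs, ddof=1) / np.sqrt(k)),
            float(np.mean(bss)), float(np.std(bss, ddof=1) / np.sqrt(k)),
            float(np.mean(tons)), float(np.std(tons, ddof=1) / np.sqrt(k)),
            float(np.mean(toffs)), float(np.std(toffs, ddof=1) / np.sqrt(k)),
            int(np.sum(counts)), "ok",
        ))
    return pd.DataFrame(
        rows,
        columns=["leakage", "bf", "bf_se", "bs", "bs_se", "tau_on", "tau_on_se",
                 "tau_off", "tau_off_se", "n_bursts", "status"],
    )
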