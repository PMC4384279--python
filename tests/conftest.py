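"""Shared fixtures: named worked-example parameter sets and reusable trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from leaky_telegraph import GeneModelParams
from leaky_telegraph.ssa import simulate

# Parameter sets from the worked examples (rates normalized by d).
FREE_MEAN_SETS = {
    "green": GeneModelParams(gamma1=0.1, gamma0=0.1, f=0.01, lambda1=40, lambda0=0),
    "red": GeneModelParams(gamma1=0.2, gamma0=0.1, f=0.0, lambda1=40, lambda0=0),
    "black": GeneModelParams(gamma1=0.1, gamma0=0.2, f=0.0, lambda1=40, lambda0=0),
    "blue": GeneModelParams(gamma1=0.1, gamma0=0.1, f=0.0, lambda1=30, lambda0=0),
}

#: No feedback; bimodal at zero leakage, unimodal by leakage 25.
NO_FEEDBACK = GeneModelParams(gamma1=0.2, gamma0=0.1, f=0.0, lambda1=40, lambda0=0)
#: Negative feedback.
NEG_FEEDBACK = GeneModelParams(gamma1=0.2, gamma0=0.1, f=0.1, lambda1=40, lambda0=0)
#: Positive feedback (D0 is the active state; lambda1 is the leakage).
POS_FEEDBACK = GeneModelParams(gamma1=0.5, gamma0=0.1, f=0.1, lambda1=0, lambda0=40)

#: Base of the fixed-mean compensation scans.
COMPENSATION_BASE = GeneModelParams(gamma1=0.1, gamma0=0.1, f=0.0, lambda1=40, lambda0=0)


def oracle_grid() -> list[GeneModelParams]:
    """>= 30 parameter sets spanning the worked-example regimes, for the
    analytic-vs-CME equivalence and moment-consistency checks."""
    grid: list[GeneModelParams] = []
    for base in FREE_MEAN_SETS.values():
        for lam0 in (0.0, 1.0, 2.0, 5.0, 10.0):
            grid.append(base.replace(lambda0=lam0))
    for lam0 in (0.0, 5.0, 15.0, 25.0):
        grid.append(NO_FEEDBACK.replace(lambda0=lam0))
    for lam0 in (0.0, 5.0, 10.0):
        grid.append(NEG_FEEDBACK.replace(lambda0=lam0))
    for lam1 in (0.0, 5.0, 10.0):
        grid.append(POS_FEEDBACK.replace(lambda1=lam1))
    return grid


@pytest.fixture(scope="session")
def no_feedback_trajectory():
    """Long no-feedback run at the bimodal parameter set, reused by the
    histogram, burst and dwell-time tests."""
    return simulate(NO_FEEDBACK, t_end=1e5, seed=20240917)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
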