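"""Truncated chemical-master-equation steady state (brute-force oracle).

The CME for the network lives on the countable state space
{(D0, n), (D1, n) : n >= 0}.  Truncating at n = N and suppressing
synthesis out of n = N (reflecting truncation) keeps the generator a
proper stochastic generator, so its one-dimensional null space is a
probability vector.  This module solves for that vector with a sparse
direct solve and serves as the independent ground truth for every
analytic result in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import InvalidParameterError, TruncationError
from .params import GeneModelParams, normalize

__all__ = ["PromoterResolvedPMF", "build_generator", "steady_state"]

logger = logging.getLogger(__name__)

_TAIL_TOL = 1e-8
_MAX_DOUBLINGS = 3


@dataclass(frozen=True)
class PromoterResolvedPMF:
    """Stationary mass split by promoter state.

    ``p0[n]`` (``p1[n]``) is the joint probability of n product
    molecules with the promoter in D0 (D1).  The marginal over the
    promoter reproduces the gene-product distribution.
    """

    p0: np.ndarray
    p1: np.ndarray
    params: GeneModelParams | None = field(default=None, compare=False)

    @property
    def support_max(self) -> int:
        return len(self.p0) - 1

    def marginal(self):
        from .analytic import DiscretePMF

        return DiscretePMF(probs=self.p0 + self.p1, source="cme", params=self.params)


def build_generator(params: GeneModelParams, n_max: int) -> sparse.csc_matrix:
    """Sparse generator of the truncated chain, column-stochastic form.

    States are ordered ``(s, n) -> s*(n_max+1) + n`` with s in {0, 1}
    the promoter state.  Entry ``[i, j]`` holds the rate of the jump
    j -> i; every column sums to zero.  Transitions:

    - (D0, n) -> (D1, n) at gamma1
    - (D1, n) -> (D0, n) at gamma0 + f*n
    - (D0, n) -> (D0, n+1) at lambda0, (D1, n) -> (D1, n+1) at lambda1
      (suppressed at n = n_max)
    - (Ds, n) -> (Ds, n-1) at d*n
    """
    if n_max < 1:
        raise InvalidParameterError(f"n_max must be >= 1, got {n_max}")
    p = normalize(params)
    size = n_max + 1

    def idx(s: int, n: int) -> int:
        return s * size + n

    rows, cols, vals = [], [], []

    def add(src: int, dst: int, rate: float) -> None:
        if rate == 0.0:
            return
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for n in range(size):
        add(idx(0, n), idx(1, n), p.gamma1)
        add(idx(1, n), idx(0, n), p.gamma0 + p.f * n)
        if n < n_max:
            add(idx(0, n), idx(0, n + 1), p.lambda0)
            add(idx(1, n), idx(1, n + 1), p.lambda1)
        if n > 0:
            add(idx(0, n), idx(0, n - 1), p.d * n)
            add(idx(1, n), idx(1, n - 1), p.d * n)

    gen = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(2 * size, 2 * size)
    ).tocsc()
    return gen


def _initial_n_max(params: GeneModelParams) -> int:
    # The stationary mean cannot exceed max(lambda0, lambda1)/d and the
    # conditional laws are near-Poisson, so mean + 10*sqrt(mean) with a
    # floor of 50 is a safe starting truncation before escalation.
    p = normalize(params)
    nu = max(p.lambda0, p.lambda1, 1.0)
    return max(50, math.ceil(nu + 10.0 * math.sqrt(nu)))


def _solve_null_space(gen: sparse.csc_matrix) -> np.ndarray:
    # Replace the last balance equation with the normalization row
    # sum(pi) = 1: deterministic and exact to solver tolerance.
    m = gen.tolil(copy=True)
    m[-1, :] = 1.0
    rhs = np.zeros(gen.shape[0])
    rhs[-1] = 1.0
    pi = spsolve(m.tocsc(), rhs)
    pi = np.asarray(pi, dtype=float)
    pi[np.abs(pi) < 1e-300] = 0.0
    neg = pi[pi < 0]
    if neg.size and neg.min() < -1e-12:
        raise TruncationError(
            f"steady-state solve produced negative mass {neg.min():.3e}"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def steady_state(
    params: GeneModelParams, n_max: int | str = "auto"
) -> PromoterResolvedPMF:
    """Stationary distribution of the truncated CME.

    The truncation ``n_max`` is escalated (doubled, at most three
    times) until the marginal mass at the boundary state falls below
    1e-8, guaranteeing the reflecting truncation does not distort the
    bulk of the distribution.

    Raises
    ------
    TruncationError
        If the boundary mass is still above tolerance after escalation.
    """
    p = normalize(params)
    if p.gamma1 == 0 and p.lambda0 == 0:
        # The chain is then absorbed in (D0|D1-less) states; still solvable,
        # but the "unique null vector" guarantee needs gamma1 > 0.
        logger.warning("gamma1 = 0: truncated chain may be reducible")
    n = _initial_n_max(p) if n_max == "auto" else int(n_max)
    for attempt in range(_MAX_DOUBLINGS + 1):
        gen = build_generator(p, n)
        pi = _solve_null_space(gen)
        size = n + 1
        p0, p1 = pi[:size], pi[size:]
        boundary = p0[-1] + p1[-1]
        if boundary < _TAIL_TOL:
            return PromoterResolvedPMF(p0=p0, p1=p1, params=p)
        if attempt < _MAX_DOUBLINGS:
            logger.info(
                "boundary mass %.2e at n_max=%d; doubling truncation", boundary, n
            )
            n *= 2
    raise TruncationError(
        f"boundary mass {boundary:.3e} still above {_TAIL_TOL} at n_max={n}"
    )
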