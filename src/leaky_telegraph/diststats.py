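"""Distribution-level statistics: moments, distances, mode counting.

Mode counting implements the committed peak convention used by the
modality analyses: a mode is a strict local maximum of the pmf, after
(i) discarding indices carrying less than ``floor_frac`` of the peak
mass (suppresses spurious tail modes from floating-point ripple) and
(ii) merging near-equal plateaus into a single candidate reported at
its leftmost index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytic import DiscretePMF, MomentSummary
from .errors import DomainError, InvalidParameterError

__all__ = ["ModalityReport", "pmf_moments", "total_variation", "count_modes"]


@dataclass(frozen=True)
class ModalityReport:
    """Number and location of the peaks of a discrete distribution."""

    n_modes: int
    mode_locations: tuple[int, ...]
    mode_masses: tuple[float, ...]


def pmf_moments(dist: DiscretePMF) -> MomentSummary:
    """Mean, variance and noise intensity by direct summation.

    The numerical twin of the generating-function moments; the two must
    agree wherever both are defined.
    """
    probs = np.asarray(dist.probs, dtype=float)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise InvalidParameterError(f"pmf not normalized (sum = {total!r})")
    n = np.arange(len(probs))
    mean = float(n @ probs) / total
    variance = float(((n - mean) ** 2) @ probs) / total
    if mean <= 0.0:
        raise DomainError("mean expression is zero; noise undefined")
    gp = mean
    gpp = float((n * (n - 1)) @ probs) / total
    return MomentSummary(
        mean=mean, variance=variance, noise=variance / mean**2,
        gprime=gp, gdoubleprime=gpp,
    )


def total_variation(p: DiscretePMF | np.ndarray, q: DiscretePMF | np.ndarray) -> float:
    """Total variation distance, supports aligned by zero-padding."""
    pa = np.asarray(p.probs if isinstance(p, DiscretePMF) else p, dtype=float)
    qa = np.asarray(q.probs if isinstance(q, DiscretePMF) else q, dtype=float)
    n = max(len(pa), len(qa))
    a = np.zeros(n)
    b = np.zeros(n)
    a[: len(pa)] = pa
    b[: len(qa)] = qa
    return 0.5 * float(np.abs(a - b).sum())


def count_modes(
    dist: DiscretePMF | np.ndarray,
    floor_frac: float = 1e-4,
    flat_tol: float = 1e-12,
) -> ModalityReport:
    """Count the peaks (strict local maxima) of a discrete distribution.

    The support boundaries count: n = 0 is a mode when probs[0] >
    probs[1], and symmetrically at the truncation edge.  Invariant to
    rescaling all masses by a positive constant.
    """
    probs = np.asarray(dist.probs if isinstance(dist, DiscretePMF) else dist,
                       dtype=float)
    if len(probs) == 0 or probs.max() <= 0:
        raise InvalidParameterError("empty or zero pmf")
    keep = probs >= floor_frac * probs.max()
    locations: list[int] = []
    masses: list[float] = []

    # Contiguous kept segments are analyzed independently; a segment
    # edge behaves like a support boundary.
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise InvalidParameterError("floor_frac removed all mass")
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for seg in splits:
        vals = probs[seg]
        # Merge plateaus: group consecutive entries differing < flat_tol.
        groups: list[tuple[int, float]] = []  # (leftmost index, value)
        for pos, v in zip(seg, vals):
            if groups and abs(v - groups[-1][1]) < flat_tol:
                continue
            groups.append((int(pos), float(v)))
        for k, (pos, v) in enumerate(groups):
            left_ok = k == 0 or v > groups[k - 1][1]
            right_ok = k == len(groups) - 1 or v > groups[k + 1][1]
            if left_ok and right_ok:
                locations.append(pos)
                masses.append(v)
    return ModalityReport(
        n_modes=len(locations),
        mode_locations=tuple(locations),
        mode_masses=tuple(masses),
    )
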