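"""Burst frequency and burst size, theoretical and from trajectories.

Bursts are delimited by the promoter state, not by copy-number
heuristics: a burst is one complete dwell period in the ON state (the
state with the larger synthesis rate), its size the number of synthesis
events fired during that period, and the burst frequency the rate of
OFF -> ON transitions,

    <BF> = 1 / tau_OFF,     <BS> = k_transcription * tau_ON.

Without feedback the dwell times are exponential, so in the
negative-feedback labeling (D1 ON): tau_OFF = 1/gamma1, tau_ON =
1/gamma0, <BF> = gamma1 and <BS> = lambda1/gamma0; in the mirrored
positive labeling (D0 ON): <BF> = gamma0 and <BS> = lambda0/gamma1.
With feedback the ON dwell (negative labeling) or OFF dwell (positive
labeling) is product-dependent and only the empirical estimator
applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UnsupportedRegimeError
from .params import GeneModelParams, feedback_labeling, normalize
from .ssa import CHANNEL_SYNTH_D0, CHANNEL_SYNTH_D1, Trajectory

__all__ = ["BurstSummary", "theoretical_burst", "empirical_burst"]

_MIN_ON_PERIODS = 10


@dataclass(frozen=True)
class BurstSummary:
    """Mean burst frequency/size and mean promoter dwell times."""

    mean_bf: float
    mean_bs: float
    tau_on: float
    tau_off: float
    n_bursts: int = 0


def theoretical_burst(params: GeneModelParams) -> BurstSummary:
    """Closed-form burst statistics, valid only without feedback.

    Raises
    ------
    UnsupportedRegimeError
        If f != 0 (use :func:`empirical_burst` on a simulated
        trajectory) or if the ON state cannot be resolved.
    """
    p = normalize(params)
    if p.f != 0.0:
        raise UnsupportedRegimeError(
            "closed-form burst statistics hold only for f = 0; "
            "use empirical_burst on a simulated trajectory"
        )
    label = feedback_labeling(p)
    if label == "constitutive":
        raise UnsupportedRegimeError(
            "lambda1 == lambda0: no ON state is resolvable"
        )
    if label == "negative":
        if p.gamma1 <= 0 or p.gamma0 <= 0:
            raise UnsupportedRegimeError("dwell times require gamma1, gamma0 > 0")
        return BurstSummary(
            mean_bf=p.gamma1, mean_bs=p.lambda1 / p.gamma0,
            tau_on=1.0 / p.gamma0, tau_off=1.0 / p.gamma1,
        )
    if p.gamma1 <= 0 or p.gamma0 <= 0:
        raise UnsupportedRegimeError("dwell times require gamma1, gamma0 > 0")
    return BurstSummary(
        mean_bf=p.gamma0, mean_bs=p.lambda0 / p.gamma1,
        tau_on=1.0 / p.gamma1, tau_off=1.0 / p.gamma0,
    )


def dwell_intervals(
    traj: Trajectory, burn_in: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Complete (ON durations, OFF durations) after burn-in.

    ON is the promoter state with the larger synthesis rate.  The
    first and last dwell intervals are discarded as incomplete (their
    start or end is censored by the observation window).
    """
    on_state = 1 if traj.params.lambda1 >= traj.params.lambda0 else 0
    if burn_in is None:
        burn_in = 0.1 * traj.t_end
    times = traj.times
    states = traj.promoter_states
    start = int(np.searchsorted(times, burn_in, side="left"))
    times = times[start:]
    states = states[start:]
    if len(times) < 3:
        raise InsufficientDataError("too few events after burn_in")
    change = np.flatnonzero(np.diff(states.astype(np.int8)) != 0) + 1
    if len(change) < 3:
        raise InsufficientDataError("fewer than two promoter switches after burn_in")
    seg_start = times[change[:-1]]
    seg_end = times[change[1:]]
    seg_state = states[change[:-1]]
    durations = seg_end - seg_start
    on = durations[seg_state == on_state]
    off = durations[seg_state != on_state]
    return on, off


def empirical_burst(
    traj: Trajectory, params: GeneModelParams | None = None,
    burn_in: float | None = None,
) -> BurstSummary:
    """Burst statistics extracted from a baseline-variant trajectory.

    tau_ON/tau_OFF are means of complete dwell intervals; BF is the
    reciprocal of the mean OFF dwell time (the rate of burst initiation
    per unit time spent OFF); BS is the mean number of synthesis events
    fired during complete ON periods (counted from the reaction-channel
    log, so interleaved degradation does not bias it).

    Raises
    ------
    InsufficientDataError
        With fewer than 10 complete ON periods.
    """
    p = normalize(params) if params is not None else traj.params
    on_state = 1 if p.lambda1 >= p.lambda0 else 0
    synth_channel = CHANNEL_SYNTH_D1 if on_state == 1 else CHANNEL_SYNTH_D0
    if burn_in is None:
        burn_in = 0.1 * traj.t_end

    times = traj.times
    states = traj.promoter_states.astype(np.int8)
    channels = traj.channels
    start = int(np.searchsorted(times, burn_in, side="left"))

    change = np.flatnonzero(np.diff(states[start:]) != 0) + start + 1
    if len(change) < 3:
        raise InsufficientDataError("fewer than two promoter switches after burn_in")
    seg_idx_start = change[:-1]
    seg_idx_end = change[1:]
    seg_state = states[seg_idx_start]
    durations = times[seg_idx_end] - times[seg_idx_start]
    on_mask = seg_state == on_state
    on_durations = durations[on_mask]
    n_on = int(on_mask.sum())
    if n_on < _MIN_ON_PERIODS:
        raise InsufficientDataError(
            f"only {n_on} complete ON periods (need >= {_MIN_ON_PERIODS})"
        )
    # Synthesis events inside each complete ON period, via cumulative
    # counts of the ON-state synthesis channel.
    cum_synth = np.concatenate([[0], np.cumsum(channels == synth_channel)])
    events_per_segment = cum_synth[seg_idx_end] - cum_synth[seg_idx_start]
    bs = float(events_per_segment[on_mask].mean())

    tau_on = float(on_durations.mean())
    off_durations = durations[~on_mask]
    tau_off = float(off_durations.mean()) if off_durations.size else math.nan
    bf = 1.0 / tau_off if tau_off > 0 else math.nan
    return BurstSummary(
        mean_bf=bf, mean_bs=bs, tau_on=tau_on, tau_off=tau_off, n_bursts=n_on
    )
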