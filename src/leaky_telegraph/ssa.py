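"""Exact stochastic simulation (Gillespie direct method) of the network.

Three reaction schemes are supported:

``baseline``
    The model proper: two promoter states, catalytic feedback
    (D1 + P -> D0 + P at rate f per molecule, the product is not
    consumed), synthesis lambda1/lambda0 by state, linear degradation.

``slow_binding``
    The feedback transition proceeds through an explicit
    transcription-factor-DNA complex: D1 + P -> D0B at rate f per
    molecule sequesters one product molecule; the complex releases it
    on dissociation, D0B -> D0 + P at rate k_off.  Spontaneous
    switching (gamma1, gamma0) is unchanged; D0B transcribes at the
    leak rate like D0.  As k_off grows large the sequestered interval
    vanishes and the scheme converges to the baseline.

``two_stage``
    Transcription and translation resolved separately: Ds -> Ds + M at
    lambda_s, M -> M + P at k_p, M -> 0 at d_m, P -> 0 at d, with the
    protein carrying the feedback.  Default d_m = 5*d reflects mRNA
    lifetimes being much shorter than protein lifetimes.

Every run records each event's time, promoter state, copy number and
reaction channel, so trajectories feed both stationary histograms and
burst extraction.  Runs are bit-reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigurationError, InsufficientDataError, InvalidParameterError
from .params import GeneModelParams, normalize

__all__ = [
    "Trajectory",
    "SlowBindingParams",
    "TwoStageParams",
    "simulate",
    "stationary_histogram",
]

VARIANTS = ("baseline", "slow_binding", "two_stage")

#: Reaction-channel codes shared by all kernels.  Channels 6 and 7 are
#: used only by the variants.
CHANNEL_D0_TO_D1 = 0       # gamma1
CHANNEL_D1_TO_D0 = 1       # gamma0 (spontaneous)
CHANNEL_FEEDBACK = 2       # f*n flip (baseline) / f*n binding (slow_binding)
CHANNEL_SYNTH_D1 = 3       # lambda1 (baseline/slow) or D1 transcription (two_stage)
CHANNEL_SYNTH_D0 = 4       # lambda0 (baseline/slow) or D0 transcription (two_stage)
CHANNEL_DEGRADE = 5        # d*n product decay
CHANNEL_RELEASE = 6        # slow_binding: D0B -> D0 + P at k_off
CHANNEL_TRANSLATE = 6      # two_stage: M -> M + P at k_p
CHANNEL_MRNA_DECAY = 7     # two_stage: M -> 0 at d_m

_CHUNK = 1 << 20


@dataclass(frozen=True)
class SlowBindingParams:
    """Dissociation rate of the sequestering TF-DNA complex."""

    k_off: float = 10.0

    def __post_init__(self) -> None:
        if self.k_off < 0:
            raise InvalidParameterError("k_off must be >= 0")


@dataclass(frozen=True)
class TwoStageParams:
    """Translation rate per mRNA and mRNA degradation rate."""

    k_p: float = 5.0
    d_m: float = 5.0

    def __post_init__(self) -> None:
        if self.k_p < 0 or self.d_m <= 0:
            raise InvalidParameterError("require k_p >= 0 and d_m > 0")


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-constant sample path of (promoter state, copy number).

    ``times[0] = 0`` records the initial condition (channel -1); each
    later entry is one reaction firing.  ``promoter_states`` is 1 in D1
    and 0 otherwise (the sequestered complex of the slow-binding
    variant reports as 0).  ``counts`` is the free product copy number;
    ``mrna`` is populated only for the two-stage variant.
    """

    times: np.ndarray
    promoter_states: np.ndarray
    counts: np.ndarray
    channels: np.ndarray
    seed: int
    variant: str
    params: GeneModelParams
    t_end: float
    mrna: np.ndarray | None = field(default=None)

    @property
    def n_events(self) -> int:
        return len(self.times) - 1


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _baseline_chunk(gamma1, gamma0, f, lam1, lam0, d, t, state, n, t_end,
                    times, states, counts, channels):
    cap = times.shape[0]
    k = 0
    while k < cap:
        if state == 1:
            a_sp = gamma0
            a_fb = f * n
            a_syn = lam1
        else:
            a_sp = gamma1
            a_fb = 0.0
            a_syn = lam0
        a_deg = d * n
        a_tot = a_sp + a_fb + a_syn + a_deg
        if a_tot <= 0.0:
            t = t_end
            return k, t, state, n, True
        t += -math.log(np.random.random()) / a_tot
        if t > t_end:
            return k, t, state, n, True
        u = np.random.random() * a_tot
        if u < a_sp:
            if state == 1:
                state = 0
                ch = CHANNEL_D1_TO_D0
            else:
                state = 1
                ch = CHANNEL_D0_TO_D1
        elif u < a_sp + a_fb:
            state = 0
            ch = CHANNEL_FEEDBACK
        elif u < a_sp + a_fb + a_syn:
            n += 1
            ch = CHANNEL_SYNTH_D1 if state == 1 else CHANNEL_SYNTH_D0
        else:
            n -= 1
            ch = CHANNEL_DEGRADE
        times[k] = t
        states[k] = state
        counts[k] = n
        channels[k] = ch
        k += 1
    return k, t, state, n, False


@njit(cache=True)
def _slow_binding_chunk(gamma1, gamma0, f, lam1, lam0, d, k_off, t, state, n,
                        t_end, times, states, counts, channels):
    # state: 0 = D0, 1 = D1, 2 = D0B (complex holding one sequestered P)
    cap = times.shape[0]
    k = 0
    while k < cap:
        a_on = gamma1 if state == 0 else 0.0
        a_off = gamma0 if state == 1 else 0.0
        a_bind = f * n if state == 1 else 0.0
        a_rel = k_off if state == 2 else 0.0
        a_syn = lam1 if state == 1 else lam0
        a_deg = d * n
        a_tot = a_on + a_off + a_bind + a_rel + a_syn + a_deg
        if a_tot <= 0.0:
            t = t_end
            return k, t, state, n, True
        t += -math.log(np.random.random()) / a_tot
        if t > t_end:
            return k, t, state, n, True
        u = np.random.random() * a_tot
        if u < a_on:
            state = 1
            ch = CHANNEL_D0_TO_D1
        elif u < a_on + a_off:
            state = 0
            ch = CHANNEL_D1_TO_D0
        elif u < a_on + a_off + a_bind:
            state = 2
            n -= 1
            ch = CHANNEL_FEEDBACK
        elif u < a_on + a_off + a_bind + a_rel:
            state = 0
            n += 1
            ch = CHANNEL_RELEASE
        elif u < a_on + a_off + a_bind + a_rel + a_syn:
            n += 1
            ch = CHANNEL_SYNTH_D1 if state == 1 else CHANNEL_SYNTH_D0
        else:
            n -= 1
            ch = CHANNEL_DEGRADE
        times[k] = t
        states[k] = 1 if state == 1 else 0
        counts[k] = n
        channels[k] = ch
        k += 1
    return k, t, state, n, False


@njit(cache=True)
def _two_stage_chunk(gamma1, gamma0, f, lam1, lam0, d, k_p, d_m, t, state, mr,
                     n, t_end, times, states, counts, mrnas, channels):
    cap = times.shape[0]
    k = 0
    while k < cap:
        a_on = gamma1 if state == 0 else 0.0
        a_off = (gamma0 + f * n) if state == 1 else 0.0
        a_tx = lam1 if state == 1 else lam0
        a_tl = k_p * mr
        a_mdeg = d_m * mr
        a_pdeg = d * n
        a_tot = a_on + a_off + a_tx + a_tl + a_mdeg + a_pdeg
        if a_tot <= 0.0:
            t = t_end
            return k, t, state, mr, n, True
        t += -math.log(np.random.random()) / a_tot
        if t > t_end:
            return k, t, state, mr, n, True
        u = np.random.random() * a_tot
        if u < a_on:
            state = 1
            ch = CHANNEL_D0_TO_D1
        elif u < a_on + a_off:
            state = 0
            ch = CHANNEL_D1_TO_D0 if u < a_on + gamma0 else CHANNEL_FEEDBACK
        elif u < a_on + a_off + a_tx:
            mr += 1
            ch = CHANNEL_SYNTH_D1 if state == 1 else CHANNEL_SYNTH_D0
        elif u < a_on + a_off + a_tx + a_tl:
            n += 1
            ch = CHANNEL_TRANSLATE
        elif u < a_on + a_off + a_tx + a_tl + a_mdeg:
            mr -= 1
            ch = CHANNEL_MRNA_DECAY
        else:
            n -= 1
            ch = CHANNEL_DEGRADE
        times[k] = t
        states[k] = state
        counts[k] = n
        mrnas[k] = mr
        channels[k] = ch
        k += 1
    return k, t, state, mr, n, False


def simulate(
    params: GeneModelParams,
    t_end: float = 1e5,
    seed: int = 0,
    variant: str = "baseline",
    variant_params: SlowBindingParams | TwoStageParams | None = None,
) -> Trajectory:
    """Exact sample path of the reaction network up to ``t_end``.

    The chain starts in (D0, n=0); the transient is removed downstream
    by the burn-in of the estimators.  Two calls with the same seed are
    bit-identical.

    Raises
    ------
    ConfigurationError
        For an unknown variant tag or mismatched variant parameters.
    """
    if t_end <= 0:
        raise InvalidParameterError("t_end must be > 0")
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; one of {VARIANTS}")
    p = normalize(params)
    _seed_rng(seed)

    t, state, n, mr = 0.0, 0, 0, 0
    chunks: list[tuple[np.ndarray, ...]] = []
    done = False
    while not done:
        times = np.empty(_CHUNK)
        states = np.empty(_CHUNK, dtype=np.int8)
        counts = np.empty(_CHUNK, dtype=np.int64)
        channels = np.empty(_CHUNK, dtype=np.int8)
        if variant == "baseline":
            k, t, state, n, done = _baseline_chunk(
                p.gamma1, p.gamma0, p.f, p.lambda1, p.lambda0, p.d,
                t, state, n, t_end, times, states, counts, channels,
            )
            chunks.append((times[:k], states[:k], counts[:k], channels[:k]))
        elif variant == "slow_binding":
            vp = variant_params if variant_params is not None else SlowBindingParams()
            if not isinstance(vp, SlowBindingParams):
                raise ConfigurationError("slow_binding requires SlowBindingParams")
            k, t, state, n, done = _slow_binding_chunk(
                p.gamma1, p.gamma0, p.f, p.lambda1, p.lambda0, p.d, vp.k_off,
                t, state, n, t_end, times, states, counts, channels,
            )
            chunks.append((times[:k], states[:k], counts[:k], channels[:k]))
        else:
            vp = variant_params if variant_params is not None else TwoStageParams()
            if not isinstance(vp, TwoStageParams):
                raise ConfigurationError("two_stage requires TwoStageParams")
            mrnas = np.empty(_CHUNK, dtype=np.int64)
            k, t, state, mr, n, done = _two_stage_chunk(
                p.gamma1, p.gamma0, p.f, p.lambda1, p.lambda0, p.d,
                vp.k_p, vp.d_m,
                t, state, mr, n, t_end, times, states, counts, mrnas, channels,
            )
            chunks.append((times[:k], states[:k], counts[:k], channels[:k],
                           mrnas[:k]))

    def cat(i: int, lead) -> np.ndarray:
        return np.concatenate([[lead]] + [c[i] for c in chunks])

    times_all = cat(0, 0.0)
    states_all = cat(1, np.int8(0))
    counts_all = cat(2, np.int64(0))
    channels_all = cat(3, np.int8(-1))
    mrna_all = cat(4, np.int64(0)) if variant == "two_stage" else None
    return Trajectory(
        times=times_all,
        promoter_states=states_all,
        counts=counts_all,
        channels=channels_all,
        seed=seed,
        variant=variant,
        params=p,
        t_end=float(t_end),
        mrna=mrna_all,
    )


def stationary_histogram(traj: Trajectory, burn_in: float | None = None):
    """Time-weighted occupancy of each copy-number level after burn-in.

    Each level is weighted by the total time the trajectory spends
    there (not by the number of events), which is the unbiased
    empirical counterpart of the stationary law.  Default burn-in is
    10% of the simulated horizon.
    """
    from .analytic import DiscretePMF

    if burn_in is None:
        burn_in = 0.1 * traj.t_end
    if burn_in >= traj.t_end:
        raise InsufficientDataError("burn_in leaves no observation window")
    times = traj.times
    counts = traj.counts
    # Level held on [times[i], times[i+1]) is counts[i]; the final level
    # extends to t_end.
    bounds = np.append(times, traj.t_end)
    starts = np.maximum(bounds[:-1], burn_in)
    ends = np.maximum(bounds[1:], burn_in)
    durations = ends - starts
    mask = durations > 0
    if not mask.any():
        raise InsufficientDataError("no events after burn_in")
    weights = np.bincount(counts[mask], weights=durations[mask])
    return DiscretePMF(
        probs=weights / weights.sum(), source="empirical", params=traj.params
    )
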