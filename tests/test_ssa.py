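"""Gillespie simulator: exactness, reproducibility, variants."""

import numpy as np
import pytest

from leaky_telegraph import GeneModelParams, stationary_pmf
from leaky_telegraph.diststats import pmf_moments, total_variation
from leaky_telegraph.errors import ConfigurationError, InsufficientDataError
from leaky_telegraph.params import normalize
from leaky_telegraph.ssa import (
    SlowBindingParams,
    Trajectory,
    TwoStageParams,
    simulate,
    stationary_histogram,
)

from conftest import NO_FEEDBACK, NEG_FEEDBACK


def _synthetic_trajectory(times, states, counts, t_end):
    """Hand-built trajectory for estimator unit tests (synthetic)."""
    n = len(times)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        promoter_states=np.asarray(states, dtype=np.int8),
        counts=np.asarray(counts, dtype=np.int64),
        channels=np.full(n, -1, dtype=np.int8),
        seed=0,
        variant="baseline",
        params=normalize(NO_FEEDBACK),
        t_end=t_end,
    )


class TestSimulate:
    def test_same_seed_bit_identical(self):
        a = simulate(NO_FEEDBACK, t_end=200.0, seed=11)
        b = simulate(NO_FEEDBACK, t_end=200.0, seed=11)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.channels, b.channels)

    def test_different_seeds_differ(self):
        a = simulate(NO_FEEDBACK, t_end=200.0, seed=11)
        b = simulate(NO_FEEDBACK, t_end=200.0, seed=12)
        assert not np.array_equal(a.times, b.times)

    def test_counts_nonnegative_and_unit_steps(self):
        traj = simulate(NEG_FEEDBACK.replace(lambda0=5.0), t_end=500.0, seed=3)
        assert traj.counts.min() >= 0
        steps = np.diff(traj.counts)
        assert set(np.unique(steps)).issubset({-1, 0, 1})
        # Promoter flips never change the count in the baseline scheme.
        flips = np.flatnonzero(np.diff(traj.promoter_states) != 0) + 1
        assert np.all(traj.counts[flips] == traj.counts[flips - 1])

    def test_constitutive_time_average_near_rate(self):
        p = GeneModelParams(0.2, 0.1, 0.0, 5.0, 5.0)
        traj = simulate(p, t_end=1e4, seed=5)
        mean = pmf_moments(stationary_histogram(traj)).mean
        # Poisson(5) with ~1e4 correlation-time-1 samples: 3 s.e. band.
        assert mean == pytest.approx(5.0, abs=3 * np.sqrt(5.0 / 1e4) * 3)

    def test_pure_decay_monotone_to_zero(self):
        p = GeneModelParams(0.2, 0.1, 0.0, 0.0, 0.0)
        traj = simulate(p, t_end=100.0, seed=1)
        assert np.all(np.diff(traj.counts) <= 0)
        assert traj.counts[-1] == 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate(NO_FEEDBACK, t_end=1.0, seed=0, variant="spatial")

    def test_histogram_matches_analytic_law(self):
        traj = simulate(NO_FEEDBACK.replace(lambda0=25.0), t_end=1e5, seed=8)
        hist = stationary_histogram(traj)
        assert total_variation(hist, stationary_pmf(NO_FEEDBACK.replace(lambda0=25.0))) < 0.02


class TestStationaryHistogram:
    def test_point_mass_for_constant_trajectory(self):
        traj = _synthetic_trajectory([0.0, 1.0], [0, 0], [3, 3], t_end=10.0)
        hist = stationary_histogram(traj, burn_in=0.0)
        assert hist.probs[3] == pytest.approx(1.0)

    def test_time_weighting_not_event_weighting(self):
        # n=0 for t in [0, 2.5), n=1 for [2.5, 10): occupancy (0.25, 0.75).
        traj = _synthetic_trajectory([0.0, 2.5], [0, 0], [0, 1], t_end=10.0)
        hist = stationary_histogram(traj, burn_in=0.0)
        assert hist.probs[0] == pytest.approx(0.25)
        assert hist.probs[1] == pytest.approx(0.75)

    def test_burn_in_beyond_horizon_rejected(self):
        traj = _synthetic_trajectory([0.0, 1.0], [0, 0], [0, 1], t_end=10.0)
        with pytest.raises(InsufficientDataError):
            stationary_histogram(traj, burn_in=10.0)


class TestVariants:
    def test_slow_binding_fast_dissociation_recovers_baseline(self):
        p = NEG_FEEDBACK.replace(lambda0=5.0)
        base = stationary_histogram(simulate(p, t_end=3e4, seed=21))
        fast = stationary_histogram(
            simulate(p, t_end=3e4, seed=22, variant="slow_binding",
                     variant_params=SlowBindingParams(k_off=500.0))
        )
        assert total_variation(base, fast) < 0.03

    def test_slow_binding_conserves_product_through_complex(self):
        traj = simulate(NEG_FEEDBACK, t_end=500.0, seed=4, variant="slow_binding",
                        variant_params=SlowBindingParams(k_off=0.5))
        assert traj.counts.min() >= 0

    def test_two_stage_leakage_reduces_protein_noise(self):
        p = NEG_FEEDBACK
        vp = TwoStageParams(k_p=5.0, d_m=5.0)
        noises = []
        for lam0 in (0.0, 10.0):
            traj = simulate(p.replace(lambda0=lam0), t_end=2e4, seed=31,
                            variant="two_stage", variant_params=vp)
            noises.append(pmf_moments(stationary_histogram(traj)).noise)
        assert noises[1] < noises[0]

    def test_two_stage_records_mrna(self):
        traj = simulate(NO_FEEDBACK, t_end=100.0, seed=2, variant="two_stage")
        assert traj.mrna is not None
        assert traj.mrna.min() >= 0
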