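"""Compensation solving and the scan drivers."""

import numpy as np
import pytest

from leaky_telegraph import GeneModelParams, moments, steady_state
from leaky_telegraph.diststats import pmf_moments
from leaky_telegraph.errors import ConfigurationError, InfeasiblePointError
from leaky_telegraph.experiments import (
    CompensationMode,
    burst_scan,
    modality_scan,
    noise_vs_leakage_scan,
    solve_compensation,
)

from conftest import COMPENSATION_BASE, NO_FEEDBACK, NEG_FEEDBACK, POS_FEEDBACK


class TestSolveCompensation:
    def test_zero_leakage_is_identity(self):
        fixed = moments(COMPENSATION_BASE).mean
        for target in ("gamma1_down", "gamma0_up", "f_up", "lambda1_down"):
            solved = solve_compensation(COMPENSATION_BASE, 0.0,
                                        CompensationMode(target, fixed))
            assert solved.as_dict() == pytest.approx(COMPENSATION_BASE.as_dict(), abs=1e-8)

    def test_gamma1_matches_algebraic_solution(self):
        # At f = 0 the mean is (lambda0*gamma0 + lambda1*gamma1)/(gamma0+gamma1);
        # solving for gamma1 in closed form is the independent oracle.
        fixed, leak = 20.0, 5.0
        solved = solve_compensation(COMPENSATION_BASE, leak,
                                    CompensationMode("gamma1_down", fixed))
        g0, l1 = COMPENSATION_BASE.gamma0, COMPENSATION_BASE.lambda1
        expected = g0 * (fixed - leak) / (l1 - fixed)
        assert solved.gamma1 == pytest.approx(expected, rel=1e-8)
        assert moments(solved).mean == pytest.approx(fixed, rel=1e-8)

    def test_f_up_mean_verified_by_cme_oracle(self):
        fixed = moments(COMPENSATION_BASE).mean
        solved = solve_compensation(COMPENSATION_BASE, 5.0, CompensationMode("f_up", fixed))
        oracle_mean = pmf_moments(steady_state(solved).marginal()).mean
        assert oracle_mean == pytest.approx(fixed, rel=1e-6)

    def test_unreachable_mean_is_infeasible(self):
        with pytest.raises(InfeasiblePointError):
            # Mean above lambda1 cannot be reached by slowing gamma0.
            solve_compensation(COMPENSATION_BASE, 0.0, CompensationMode("gamma0_up", 80.0))


class TestNoiseScan:
    def test_single_point_equals_base_moments(self):
        table = noise_vs_leakage_scan(NO_FEEDBACK, np.array([5.0]))
        m = moments(NO_FEEDBACK.replace(lambda0=5.0))
        assert table.loc[0, "noise"] == pytest.approx(m.noise, rel=1e-12)
        assert table.loc[0, "mean"] == pytest.approx(m.mean, rel=1e-12)

    def test_fixed_mean_rows_keep_the_mean(self):
        fixed = moments(COMPENSATION_BASE).mean
        table = noise_vs_leakage_scan(
            COMPENSATION_BASE, np.linspace(0.0, 10.0, 5),
            CompensationMode("gamma0_up", fixed),
        )
        ok = table[table["path"] != "infeasible"]
        assert np.allclose(ok["mean"], fixed, rtol=1e-8)

    def test_infeasible_points_recorded_as_gaps(self):
        # Fixing the mean at 20 by lowering gamma1 fails once the
        # leakage alone pushes the mean above the target.
        table = noise_vs_leakage_scan(
            COMPENSATION_BASE, np.linspace(0.0, 30.0, 7),
            CompensationMode("gamma1_down", 20.0),
        )
        assert (table["path"] == "infeasible").any()
        assert (table["path"] != "infeasible").any()

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            noise_vs_leakage_scan(NO_FEEDBACK, np.array([]))


class TestModalityScan:
    def test_no_feedback_two_to_one(self):
        table = modality_scan(NO_FEEDBACK, np.array([0.0, 25.0]))
        assert table["n_modes"].tolist() == [2, 1]

    def test_positive_feedback_two_to_one(self):
        table = modality_scan(POS_FEEDBACK, np.array([0.0, 10.0]))
        assert table["n_modes"].tolist() == [2, 1]

    def test_negative_feedback_single_peak_moves_out(self):
        table = modality_scan(NEG_FEEDBACK, np.array([0.0, 10.0]))
        assert table["n_modes"].tolist() == [1, 1]
        first = table.loc[0, "mode_locations"][0]
        last = table.loc[1, "mode_locations"][0]
        assert last > first


class TestBurstScan:
    def test_aggregates_over_seeds_with_errors(self):
        table = burst_scan(NO_FEEDBACK, np.array([0.0, 10.0]), seeds=(0, 1, 2),
                           t_end=5e3)
        assert (table["status"] == "ok").all()
        assert (table["bf_se"] > 0).all()
        assert table["n_bursts"].min() > 10

    def test_reproducible_given_seeds(self):
        a = burst_scan(NO_FEEDBACK, np.array([0.0]), seeds=(5, 6), t_end=2e3)
        b = burst_scan(NO_FEEDBACK, np.array([0.0]), seeds=(5, 6), t_end=2e3)
        assert a.equals(b)
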