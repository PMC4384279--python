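"""Closed-form stationary distribution and generating-function moments."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

from leaky_telegraph import GeneModelParams, moments, stationary_pmf, steady_state
from leaky_telegraph.diststats import pmf_moments, total_variation
from leaky_telegraph.errors import DegenerateParameterError, DomainError
from leaky_telegraph.special import hyp1f1_stable

from conftest import FREE_MEAN_SETS, NO_FEEDBACK


def classical_two_state_pmf(lam: float, g1: float, g0: float, n_max: int) -> np.ndarray:
    """Independent oracle: the no-leakage, no-feedback telegraph law
    P(n) proportional to (lam^n/n!) (g1)_n/(g0+g1)_n 1F1(g1+n, g0+g1+n; -lam)."""
    ns = np.arange(n_max + 1)
    logpoch = gammaln(g1 + ns) - gammaln(g1) - (gammaln(g0 + g1 + ns) - gammaln(g0 + g1))
    body = np.exp(ns * np.log(lam) - gammaln(ns + 1.0) + logpoch)
    tail = np.array([hyp1f1_stable(g1 + n, g0 + g1 + n, -lam) for n in ns])
    probs = body * tail
    return probs / probs.sum()


class TestStationaryPmf:
    def test_reduces_to_classical_two_state_law(self):
        pmf = stationary_pmf(NO_FEEDBACK)
        ref = classical_two_state_pmf(40.0, 0.2, 0.1, pmf.support_max)
        assert np.abs(pmf.probs - ref).max() < 1e-8

    def test_leaky_pmf_matches_cme_oracle(self):
        p = NO_FEEDBACK.replace(lambda0=5.0)
        pmf = stationary_pmf(p)
        marg = steady_state(p, n_max=200).marginal()
        assert total_variation(pmf, marg) < 1e-6

    def test_constitutive_limit_is_poisson(self):
        p = GeneModelParams(0.2, 0.1, 0.0, 5.0, 5.0)
        pmf = stationary_pmf(p)
        assert pmf.source == "poisson"
        assert pmf.probs[0] == pytest.approx(np.exp(-5.0), rel=1e-12)
        ref = poisson.pmf(np.arange(pmf.support_max + 1), 5.0)
        assert total_variation(pmf.probs, ref / ref.sum()) < 1e-10

    def test_mass_sums_to_one_before_forced_renormalization(self):
        for p in [NO_FEEDBACK, NO_FEEDBACK.replace(lambda0=25.0),
                  GeneModelParams(0.2, 0.1, 0.1, 40.0, 10.0)]:
            pmf = stationary_pmf(p)
            assert abs(pmf.renorm_residual) < 1e-6

    def test_fast_switching_approaches_poisson(self):
        # gamma1 -> infinity with gamma0 = 0 keeps the promoter ON:
        # the law converges to Poisson(lambda1).
        p = GeneModelParams(1e3, 0.0, 0.0, 40.0, 0.0)
        pmf = stationary_pmf(p)
        ref = poisson.pmf(np.arange(pmf.support_max + 1), 40.0)
        assert total_variation(pmf.probs, ref / ref.sum()) < 1e-3

    def test_positive_feedback_regime_routed_to_oracle_when_needed(self):
        p = GeneModelParams(0.5, 0.1, 0.1, 10.0, 40.0)  # lam < 0
        pmf = stationary_pmf(p)
        marg = steady_state(p, n_max=max(200, pmf.support_max)).marginal()
        assert total_variation(pmf, marg) < 1e-6

    def test_degenerate_parameters_refused(self):
        # lambda1 = lambda0 with f > 0 makes R = -f*lambda0... which is
        # fine; but lambda1 - lambda0 = f*lambda0 makes R = 0 exactly.
        p = GeneModelParams(0.2, 0.1, 0.5, 15.0, 10.0)  # R = 5 - 5 = 0
        with pytest.raises(DegenerateParameterError):
            stationary_pmf(p)


class TestMoments:
    def test_no_feedback_mean_closed_form(self):
        # At f = 0 the mean is the occupancy-weighted synthesis rate.
        for lam0 in (0.0, 5.0, 10.0):
            p = GeneModelParams(0.2, 0.1, 0.0, 40.0, lam0)
            expected = (lam0 * 0.1 + 40.0 * 0.2) / 0.3
            assert moments(p).mean == pytest.approx(expected, abs=1e-10)

    def test_equal_occupancy_mean(self):
        p = GeneModelParams(0.1, 0.1, 0.0, 40.0, 10.0)
        assert moments(p).mean == pytest.approx(25.0, abs=1e-10)

    def test_constitutive_noise_is_poissonian(self):
        m = moments(GeneModelParams(0.3, 0.7, 0.0, 5.0, 5.0))
        assert m.noise == pytest.approx(0.2, rel=1e-12)

    def test_zero_mean_noise_undefined(self):
        with pytest.raises((DomainError, DegenerateParameterError)):
            moments(GeneModelParams(0.2, 0.1, 0.0, 0.0, 0.0))

    @pytest.mark.parametrize("name", sorted(FREE_MEAN_SETS))
    def test_moments_match_pmf_summation(self, name):
        p = FREE_MEAN_SETS[name].replace(lambda0=3.0)
        m = moments(p)
        ms = pmf_moments(stationary_pmf(p))
        assert m.mean == pytest.approx(ms.mean, rel=1e-6)
        assert m.variance == pytest.approx(ms.variance, rel=1e-6)
        assert m.noise == pytest.approx(ms.noise, rel=1e-6)

    def test_moments_match_cme_oracle_with_feedback(self):
        p = GeneModelParams(0.2, 0.1, 0.1, 40.0, 10.0)
        m = moments(p)
        mo = pmf_moments(steady_state(p).marginal())
        assert m.mean == pytest.approx(mo.mean, rel=1e-6)
        assert m.noise == pytest.approx(mo.noise, rel=1e-6)


class TestHeadlineMonotonicity:
    def test_mean_strictly_increasing_in_leakage(self):
        grid = np.linspace(0.0, 10.0, 21)
        means = [moments(NO_FEEDBACK.replace(lambda0=l)).mean for l in grid]
        assert np.all(np.diff(means) > 0)

    @pytest.mark.parametrize("name", sorted(FREE_MEAN_SETS))
    def test_noise_strictly_decreasing_in_leakage(self, name):
        grid = np.linspace(0.0, 10.0, 21)
        noise = [moments(FREE_MEAN_SETS[name].replace(lambda0=l)).noise for l in grid]
        assert np.all(np.diff(noise) < 0)
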