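"""Unit and property tests for the ordered-probit primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import ordsurvey as osv
from ordsurvey.errors import EmptyStratumError, ParameterError
from ordsurvey.survey_io import EncodedVector


def vec(codes, dk=0, k=5, has_dk=False):
    return EncodedVector(
        ordinal_codes=np.asarray(codes, dtype=int),
        dk_count=dk,
        question_id="q",
        group="all",
        n_categories=k,
        has_dk=has_dk,
    )


class TestCategoryProbabilities:
    def test_worked_example(self, worked_params):
        p = osv.category_probabilities(worked_params)
        expected = (0.066807, 0.241731, 0.382925, 0.241731, 0.066807)
        assert p == pytest.approx(expected, abs=1e-6)

    def test_left_tail_cell(self, th5):
        p = osv.category_probabilities(osv.OrdinalParams(2.0, 0.5, th5))
        assert p[0] == pytest.approx(stats.norm.cdf(-1.0), abs=1e-9)

    def test_symmetry_about_midpoint(self, th5):
        for sigma in (0.3, 1.0, 4.0):
            p = osv.category_probabilities(osv.OrdinalParams(3.0, sigma, th5))
            assert p[0] == pytest.approx(p[4], abs=1e-12)
            assert p[1] == pytest.approx(p[3], abs=1e-12)

    def test_unordered_thresholds_rejected(self):
        bad = osv.OrdinalParams(3.0, 1.0, [1.5, 3.5, 2.5, 4.5])
        with pytest.raises(ParameterError):
            osv.category_probabilities(bad)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        mu=st.floats(-3, 9),
        sigma=st.floats(0.05, 8),
        k=st.integers(3, 7),
        u=st.tuples(*(st.floats(0.05, 0.95) for _ in range(5))),
    )
    def test_matches_numerical_integration(self, mu, sigma, k, u):
        """Each cell equals the normal mass between its thresholds (quad oracle)."""
        lo, hi = osv.fixed_threshold_bounds(k)
        free = lo + np.sort(np.array(u[: k - 3])) * (hi - lo)
        th = np.concatenate(([lo], free, [hi]))
        if np.any(np.diff(th) <= 0):
            return
        p = osv.category_probabilities(osv.OrdinalParams(mu, sigma, th))
        # finite integration windows: beyond 13 sigma the missed tail < 1e-30
        lo_edge = min(th[0], mu) - 13 * sigma
        hi_edge = max(th[-1], mu) + 13 * sigma
        bounds = np.concatenate(([lo_edge], th, [hi_edge]))
        for j in range(k):
            q, _ = integrate.quad(
                stats.norm(mu, sigma).pdf, bounds[j], bounds[j + 1], limit=200
            )
            assert p[j] == pytest.approx(q, abs=1e-8)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(mu_lo=st.floats(1, 4), bump=st.floats(0.01, 3), sigma=st.floats(0.1, 5))
    def test_stochastic_ordering_in_mu(self, th5, mu_lo, bump, sigma):
        """Raising mu never lowers P(y >= k) for any k."""
        p1 = osv.category_probabilities(osv.OrdinalParams(mu_lo, sigma, th5))
        p2 = osv.category_probabilities(osv.OrdinalParams(mu_lo + bump, sigma, th5))
        surv1 = 1.0 - np.cumsum(p1)[:-1]
        surv2 = 1.0 - np.cumsum(p2)[:-1]
        assert np.all(surv2 >= surv1 - 1e-12)

    def test_sigma_to_zero_concentrates(self, th5):
        for mu, cat in ((1.1, 0), (2.7, 2), (4.9, 4)):
            p = osv.category_probabilities(osv.OrdinalParams(mu, 1e-8, th5))
            assert p[cat] == pytest.approx(1.0, abs=1e-12)


class TestDkAdjustment:
    def test_zero_delta_is_identity(self, worked_params):
        p = osv.category_probabilities(worked_params)
        adj = osv.dk_adjusted_probabilities(0.0, p)
        assert adj[0] == 0.0
        np.testing.assert_allclose(adj[1:], p)

    def test_quarter_delta(self):
        adj = osv.dk_adjusted_probabilities(0.25, np.full(5, 0.2))
        np.testing.assert_allclose(adj, [0.25] + [0.15] * 5)

    def test_degenerate_delta_one(self):
        adj = osv.dk_adjusted_probabilities(1.0, np.full(5, 0.2))
        np.testing.assert_allclose(adj, [1.0, 0, 0, 0, 0, 0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(delta=st.floats(0, 1), mu=st.floats(0, 6), sigma=st.floats(0.1, 5))
    def test_sums_to_one(self, th5, delta, mu, sigma):
        p = osv.category_probabilities(osv.OrdinalParams(mu, sigma, th5))
        assert osv.dk_adjusted_probabilities(delta, p).sum() == pytest.approx(1.0, abs=1e-12)


class TestLogLikelihood:
    def test_worked_example(self, worked_params):
        ll = osv.log_likelihood(vec([3, 3, 1]), worked_params)
        assert ll == pytest.approx(-4.625777, abs=1e-4)
        # hand recomputation from the CDF oracle
        p = osv.category_probabilities(worked_params)
        assert ll == pytest.approx(2 * math.log(p[2]) + math.log(p[0]), abs=1e-12)

    def test_dk_channel_reduces_when_delta_zero(self, th5):
        data = vec([2, 4, 4], dk=0, has_dk=True)
        with_dk = osv.log_likelihood(data, osv.OrdinalParams(3, 1, th5, delta=0.0))
        without = osv.log_likelihood(vec([2, 4, 4]), osv.OrdinalParams(3, 1, th5))
        assert with_dk == pytest.approx(without, abs=1e-12)

    def test_single_dk_observation(self, th5):
        data = vec([], dk=1, has_dk=True)
        ll = osv.log_likelihood(data, osv.OrdinalParams(3, 1, th5, delta=0.2))
        assert ll == pytest.approx(math.log(0.2), abs=1e-12)

    def test_empty_data_refused(self, worked_params):
        with pytest.raises(EmptyStratumError):
            osv.log_likelihood(vec([]), worked_params)

    def test_dk_mismatch_refused(self, th5):
        with pytest.raises(ParameterError):
            osv.log_likelihood(vec([1, 2]), osv.OrdinalParams(3, 1, th5, delta=0.1))

    def test_zero_probability_category_floors(self, th5):
        # sigma tiny, mu in bin 3 => observing category 1 is impossible
        ll = osv.log_likelihood(vec([1]), osv.OrdinalParams(3.0, 1e-12, th5))
        assert ll <= -1e290 and np.isfinite(ll)


class TestLogPrior:
    def test_sigma_below_support(self, th5):
        spec = osv.PriorSpec.default(5)
        params = osv.OrdinalParams(3, 0.005, th5)
        assert osv.log_prior(params, spec) == -np.inf

    def test_mu_at_mode_contribution(self, th5):
        """At the prior mode the mu term is -ln(K sqrt(2 pi))."""
        spec = osv.PriorSpec.default(5)
        at_mode = osv.log_prior(osv.OrdinalParams(3.0, 1.0, th5), spec)
        shifted = osv.log_prior(osv.OrdinalParams(4.0, 1.0, th5), spec)
        # difference isolates the mu term: -(z^2)/2 with z = 1/K
        assert at_mode - shifted == pytest.approx(0.5 / 25.0, abs=1e-12)
        mu_term = -math.log(5 * math.sqrt(2 * math.pi))
        sigma_term = -math.log(spec.sigma_hi - spec.sigma_lo)
        theta_term = 2 * mu_term  # both free thetas at their prior modes
        assert at_mode == pytest.approx(mu_term + sigma_term + theta_term, abs=1e-12)

    def test_unordered_thresholds_give_minus_inf(self):
        spec = osv.PriorSpec.default(5)
        params = osv.OrdinalParams(3, 1, [1.5, 3.5, 2.5, 4.5])
        assert osv.log_prior(params, spec) == -np.inf

    def test_delta_outside_support(self, th5):
        spec = osv.PriorSpec.default(5)
        # construct via object bypass is impossible; use uniform bounds instead
        narrow = osv.PriorSpec(3.0, 5.0, 0.01, 50.0, 5.0, delta_lo=0.2, delta_hi=0.8)
        params = osv.OrdinalParams(3, 1, th5, delta=0.1)
        assert osv.log_prior(params, narrow) == -np.inf


class TestParamValidation:
    def test_extremes_must_be_fixed(self):
        with pytest.raises(ParameterError):
            osv.OrdinalParams(3, 1, [1.0, 2.5, 3.5, 4.5])

    def test_sigma_positive(self, th5):
        with pytest.raises(ParameterError):
            osv.OrdinalParams(3, -1.0, th5)

    def test_fixed_bounds_values(self):
        assert osv.fixed_threshold_bounds(5) == (1.5, 4.5)
        assert osv.fixed_threshold_bounds(6) == (1.5, 5.5)
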