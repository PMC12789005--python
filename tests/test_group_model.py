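"""Group model, country weighting and contrasts."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

import ordsurvey as osv
from ordsurvey.errors import EmptyStratumError, ParameterError
from ordsurvey.group_model import CategoryProbs, _probs_matrix
from ordsurvey.survey_io import EncodedVector


def simulate_pair(mu_r, mu_u, sigma_r, sigma_u, th, n, seed, delta_r=None, delta_u=None):
    rng = np.random.default_rng(seed)
    rural = osv.simulate_responses(osv.OrdinalParams(mu_r, sigma_r, th, delta_r), n, rng)
    urban = osv.simulate_responses(osv.OrdinalParams(mu_u, sigma_u, th, delta_u), n, rng)
    return replace(rural, group="rural"), replace(urban, group="urban")


@pytest.fixture(scope="module")
def identical_data_fit(th5):
    """One dataset used for both strata: groups are exchangeable."""
    data = osv.simulate_responses(osv.OrdinalParams(3.1, 1.0, th5), 1500, 21)
    rural = replace(data, group="rural")
    urban = replace(data, group="urban")
    cfg = osv.McmcConfig(n_chains=6, n_iterations=8000, burn_in=3000, seed=2)
    return osv.fit_group_model(rural, urban, cfg=cfg)


@pytest.fixture(scope="module")
def distinct_fit(th5):
    """Fit to data with a one-unit rural/urban gap (mu 2.5 vs 3.5)."""
    rural, urban = simulate_pair(2.5, 3.5, 1.0, 1.0, th5, 5000, seed=11)
    cfg = osv.McmcConfig(n_chains=4, n_iterations=4000, burn_in=2000, seed=1)
    return osv.fit_group_model(rural, urban, cfg=cfg)


class TestFitGroupModel:
    def test_recovers_distinct_groups(self, distinct_fit):
        table = osv.summarize(distinct_fit)
        for name, truth in (("mu_R", 2.5), ("mu_U", 3.5), ("sigma_R", 1.0), ("sigma_U", 1.0)):
            row = table.loc[name]
            assert abs(row["mean"] - truth) < 3 * row["sd"], name

    def test_identical_data_exchangeable(self, identical_data_fit):
        """With the same data in both strata, (mu_R, sigma_R) and
        (mu_U, sigma_U) have the same posterior (K-S distance < 0.05)."""
        draws = identical_data_fit
        for a, b in (("mu_R", "mu_U"), ("sigma_R", "sigma_U")):
            ks = stats.ks_2samp(draws.pooled(a), draws.pooled(b)).statistic
            assert ks < 0.05, (a, b, ks)

    def test_empty_stratum_refused(self, th5):
        empty = EncodedVector(np.array([], dtype=int), 0, "q", "rural", 5, False)
        full = EncodedVector(np.array([1, 2, 3]), 0, "q", "urban", 5, False)
        with pytest.raises(EmptyStratumError):
            osv.fit_group_model(empty, full, cfg=osv.McmcConfig(2, 100, 10, seed=0))

    def test_k_mismatch_refused(self):
        a = EncodedVector(np.array([1, 2]), 0, "q", "rural", 5, False)
        b = EncodedVector(np.array([1, 2]), 0, "q", "urban", 6, False)
        with pytest.raises(ParameterError):
            osv.fit_group_model(a, b, cfg=osv.McmcConfig(2, 100, 10, seed=0))


class TestCountryWeighting:
    def test_convex_combination_example(self):
        p_r = np.array([[0.1, 0.2, 0.4, 0.2, 0.1]])
        p_u = np.array([[0.3, 0.3, 0.2, 0.1, 0.1]])
        mixed = 0.4 * p_r + 0.6 * p_u
        np.testing.assert_allclose(mixed[0], [0.22, 0.26, 0.28, 0.14, 0.10])

    def test_wr_one_equals_rural(self, identical_data_fit):
        country = osv.country_category_posterior(identical_data_fit, 1.0)
        rural = osv.group_level_posterior(identical_data_fit, "rural")
        np.testing.assert_array_equal(country.draws, rural.draws)

    def test_mixing_linearity_exact(self, identical_data_fit):
        """Posterior mean of the mixed vector equals the same convex
        combination of the group posterior means (mixing is per-draw)."""
        w = 0.37
        country = osv.country_category_posterior(identical_data_fit, w)
        rural = osv.group_level_posterior(identical_data_fit, "rural")
        urban = osv.group_level_posterior(identical_data_fit, "urban")
        np.testing.assert_allclose(
            country.mean, w * rural.mean + (1 - w) * urban.mean, atol=1e-12
        )

    def test_identical_params_mixture_equals_group(self, th5):
        mu = np.full(200, 3.2)
        sigma = np.full(200, 1.1)
        free = np.tile([2.4, 3.6], (200, 1))
        p = _probs_matrix(mu, sigma, free, 5, None)
        draws = osv.PosteriorDraws(
            parameter_names=("mu_R", "mu_U", "sigma_R", "sigma_U", "theta_2", "theta_3"),
            draws=np.stack([mu, mu, sigma, sigma, free[:, 0], free[:, 1]], axis=1)[None, :, :],
            provenance={"K": 5, "has_dk": False},
        )
        for w in (0.0, 0.3, 1.0):
            country = osv.country_category_posterior(draws, w)
            np.testing.assert_allclose(country.draws, p, atol=1e-12)

    def test_each_draw_sums_to_one(self, identical_data_fit):
        country = osv.country_category_posterior(identical_data_fit, 0.42)
        np.testing.assert_allclose(country.draws.sum(axis=1), 1.0, atol=1e-12)

    def test_bad_weight_rejected(self, identical_data_fit):
        with pytest.raises(ParameterError):
            osv.country_category_posterior(identical_data_fit, 1.2)

    def test_dk_included_in_country_vector(self, th5):
        rural, urban = simulate_pair(
            3.0, 3.0, 1.0, 1.0, th5, 800, seed=5, delta_r=0.2, delta_u=0.1
        )
        cfg = osv.McmcConfig(n_chains=3, n_iterations=1500, burn_in=700, seed=3)
        draws = osv.fit_group_model(rural, urban, cfg=cfg)
        country = osv.country_category_posterior(draws, 0.5)
        assert country.labels[0] == "DK"
        assert country.draws.shape[1] == 6
        np.testing.assert_allclose(country.draws.sum(axis=1), 1.0, atol=1e-12)
        # DK share of the 50/50 mix sits between the group rates
        assert 0.1 < country.mean[0] < 0.22


class TestGroupContrast:
    def test_identical_data_contrast_covers_zero(self, identical_data_fit):
        table = osv.group_contrast(identical_data_fit)
        row = table.loc["mu_U - mu_R"]
        assert row["q2.5"] < 0 < row["q97.5"]
        assert not row["ci_excludes_zero"]

    def test_large_difference_flagged(self, distinct_fit):
        row = osv.group_contrast(distinct_fit).loc["mu_U - mu_R"]
        assert row["ci_excludes_zero"]
        assert abs(row["mean"] - 1.0) < 4 * row["sd"]

    def test_degenerate_equal_draws(self):
        arr = np.zeros((2, 100, 4))
        arr[:, :, 0] = arr[:, :, 1] = np.random.default_rng(0).normal(size=(2, 100))
        arr[:, :, 2] = arr[:, :, 3] = 1.0
        draws = osv.PosteriorDraws(
            parameter_names=("mu_R", "mu_U", "sigma_R", "sigma_U"),
            draws=arr,
            provenance={"K": 3, "has_dk": False},
        )
        table = osv.group_contrast(draws)
        assert table.loc["mu_U - mu_R", "mean"] == 0.0
        assert table.loc["mu_U - mu_R", "sd"] == 0.0


class TestCategoryProbsContainer:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            CategoryProbs("q", None, "rural", ("a", "b"), np.array([[0.5, 0.4]]))

    def test_export_frame_schema(self, identical_data_fit):
        frame = osv.group_level_posterior(identical_data_fit, "urban").to_frame()
        assert list(frame.columns) == [
            "country", "question", "level", "category", "mean", "median", "lower", "upper",
        ]
        assert np.isclose(frame["mean"].sum(), 1.0)
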