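"""Synthetic-survey generator and parameter-recovery machinery."""

import numpy as np
import pytest

import ordsurvey as osv
from ordsurvey.errors import ParameterError
from ordsurvey.ordinal import _loglik_from_counts, _category_counts
from ordsurvey.simulate import (
    CountryScenario,
    CovariateTruth,
    Scenario,
    default_scenario,
    load_scenario,
    save_scenario,
)


class TestSimulateResponses:
    def test_empty(self, th5):
        enc = osv.simulate_responses(osv.OrdinalParams(3, 1, th5), 0, 0)
        assert enc.n_total == 0 and enc.is_empty

    def test_frequencies_match_cell_probabilities(self, worked_params):
        enc = osv.simulate_responses(worked_params, 100_000, 42)
        freq = np.bincount(enc.ordinal_codes, minlength=6)[1:] / enc.n_total
        expected = (0.0668, 0.2417, 0.3829, 0.2417, 0.0668)
        np.testing.assert_allclose(freq, expected, atol=0.01)

    def test_all_dk_when_delta_one(self, th5):
        enc = osv.simulate_responses(osv.OrdinalParams(3, 1, th5, delta=1.0), 500, 1)
        assert enc.dk_count == 500 and enc.ordinal_codes.size == 0

    def test_dk_rate_converges(self, th5):
        enc = osv.simulate_responses(osv.OrdinalParams(3, 1, th5, delta=0.3), 50_000, 2)
        assert enc.dk_count / enc.n_total == pytest.approx(0.3, abs=0.01)

    def test_deterministic_given_seed(self, worked_params):
        a = osv.simulate_responses(worked_params, 1000, 7)
        b = osv.simulate_responses(worked_params, 1000, 7)
        np.testing.assert_array_equal(a.ordinal_codes, b.ordinal_codes)


@pytest.fixture(scope="module")
def mini_scenario(th5):
    countries = (
        CountryScenario("AA", 0.3, 50, 50),
        CountryScenario("BB", 0.6, 50, 50),
    )
    questions = (
        osv.QuestionSpec("attitude", 5, True),
        osv.QuestionSpec("covq", 5, False),
    )
    group_truth = osv.GroupParams(2.8, 3.2, 1.0, 1.1, th5, 0.2, 0.1)
    cov_truth = CovariateTruth(
        alpha=3.0, b_location=0.3, b_sex=0.4, b_age=-0.2,
        b_politics=(0.2, 0.1, -0.1, -0.2), sigma=1.0, thresholds=th5,
    )
    truths = {
        "attitude": {"AA": group_truth, "BB": group_truth},
        "covq": {"AA": cov_truth, "BB": cov_truth},
    }
    return Scenario(countries=countries, questions=questions, truths=truths, seed=5)


class TestSimulateSurvey:
    def test_counts(self, mini_scenario):
        ds = osv.simulate_survey(mini_scenario)
        assert ds.n_respondents == 200

    def test_same_seed_identical(self, mini_scenario):
        a = osv.simulate_survey(mini_scenario)
        b = osv.simulate_survey(mini_scenario)
        assert a.frame.equals(b.frame)

    def test_balanced_strata_exact(self, mini_scenario):
        ds = osv.simulate_survey(mini_scenario)
        for code in ("AA", "BB"):
            sub = ds.frame[ds.frame["country"] == code]
            assert (sub["location"] == "rural").sum() == 50
            assert (sub["sex"] == "female").sum() == 50

    def test_round_trips_through_io(self, mini_scenario, tmp_path):
        ds = osv.simulate_survey(mini_scenario)
        path = tmp_path / "sim.csv"
        osv.write_survey(ds, path)
        back = osv.read_survey(path, ds.schema)
        assert back.n_respondents == ds.n_respondents
        enc_a = osv.encode_responses(ds, "attitude", "AA", "rural")
        enc_b = osv.encode_responses(back, "attitude", "AA", "rural")
        np.testing.assert_array_equal(enc_a.ordinal_codes, enc_b.ordinal_codes)

    def test_group_frequencies_converge(self, th5):
        """Rural empirical frequencies approach the generating DK-adjusted
        cell probabilities as n grows."""
        truth = osv.GroupParams(2.6, 3.4, 1.0, 1.2, th5, 0.15, 0.05)
        scen = Scenario(
            countries=(CountryScenario("AA", 0.5, 20_000, 20_000),),
            questions=(osv.QuestionSpec("q", 5, True),),
            truths={"q": {"AA": truth}},
            seed=9,
        )
        ds = osv.simulate_survey(scen)
        enc = osv.encode_responses(ds, "q", "AA", "rural")
        p = osv.dk_adjusted_probabilities(
            0.15, osv.category_probabilities(osv.OrdinalParams(2.6, 1.0, th5))
        )
        emp = np.concatenate(
            [[enc.dk_count], np.bincount(enc.ordinal_codes, minlength=6)[1:]]
        ) / enc.n_total
        np.testing.assert_allclose(emp, p, atol=0.01)

    def test_truth_k_mismatch_rejected(self, th5):
        with pytest.raises(ParameterError, match="mismatch"):
            Scenario(
                countries=(CountryScenario("AA", 0.5, 10, 10),),
                questions=(osv.QuestionSpec("q", 6, False),),
                truths={"q": {"AA": osv.GroupParams(3, 3, 1, 1, th5)}},
                seed=0,
            )

    def test_default_scenario_shape(self):
        scen = default_scenario(n_per_group=10)
        assert len(scen.countries) == 23
        assert len(scen.questions) == 4
        ds = osv.simulate_survey(scen)
        assert ds.n_respondents == 23 * 20


class TestScenarioFiles:
    def test_yaml_round_trip(self, mini_scenario, tmp_path):
        path = tmp_path / "scenario.yaml"
        save_scenario(mini_scenario, path)
        back = load_scenario(path)
        assert back.countries == mini_scenario.countries
        assert back.questions == mini_scenario.questions
        a = osv.simulate_survey(mini_scenario)
        b = osv.simulate_survey(back)
        assert a.frame.equals(b.frame)


class TestGeneratorLikelihoodConsistency:
    def test_loglik_profile_peaks_near_truth(self, th5):
        """The average log-likelihood over a mu grid is maximised near the
        generating mu at large n (generator and likelihood agree)."""
        truth = osv.OrdinalParams(3.3, 1.0, th5)
        enc = osv.simulate_responses(truth, 50_000, 13)
        counts = _category_counts(enc.ordinal_codes, 5)
        grid = np.linspace(2.0, 4.5, 51)
        lls = [
            _loglik_from_counts(counts, 0, m, 1.0, th5, None) for m in grid
        ]
        assert abs(grid[int(np.argmax(lls))] - 3.3) <= 0.1


class TestRecoveryExperiment:
    def test_single_group_report_structure(self, th5):
        truth = osv.OrdinalParams(3.0, 1.0, th5, delta=0.1)
        cfg = osv.McmcConfig(n_chains=2, n_iterations=800, burn_in=400, seed=0)
        report = osv.recovery_experiment(truth, n=400, cfg=cfg, n_replicates=3, seed=4)
        assert list(report.table.index) == ["mu", "sigma", "theta_2", "theta_3", "delta"]
        assert set(report.table.columns) >= {"truth", "bias", "rmse", "coverage", "max_rhat"}
        assert ((report.table["coverage"].dropna() >= 0)
                & (report.table["coverage"].dropna() <= 1)).all()

    def test_bias_small_at_large_n(self, th5):
        """Truth at the prior mode, large n: posterior mean is consistent."""
        truth = osv.OrdinalParams(3.0, 1.0, th5)
        cfg = osv.McmcConfig(n_chains=3, n_iterations=2000, burn_in=1000, seed=0)
        report = osv.recovery_experiment(truth, n=20_000, cfg=cfg, n_replicates=2, seed=8)
        assert abs(report.table.loc["mu", "bias"]) < 0.03
        assert abs(report.table.loc["sigma", "bias"]) < 0.03

    def test_same_seed_same_report(self, th5):
        truth = osv.OrdinalParams(3.0, 1.0, th5)
        cfg = osv.McmcConfig(n_chains=2, n_iterations=500, burn_in=200, seed=0)
        a = osv.recovery_experiment(truth, n=200, cfg=cfg, n_replicates=2, seed=3)
        b = osv.recovery_experiment(truth, n=200, cfg=cfg, n_replicates=2, seed=3)
        assert a.table.equals(b.table)
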