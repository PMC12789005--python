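import pytest

import ordsurvey as osv


@pytest.fixture(scope="session")
def th5():
    """Default thresholds for a 5-category scale: (1.5, 2.5, 3.5, 4.5)."""
    return osv.default_thresholds(5)


@pytest.fixture(scope="session")
def worked_params(th5):
    """The hand-checked reference parameter set (mu=3, sigma=1, K=5)."""
    return osv.OrdinalParams(mu=3.0, sigma=1.0, thresholds=th5)


@pytest.fixture
def tiny_survey_file(tmp_path):
    """A 4-respondent canonical survey table with one DK question."""
    text = (
        "respondent_id,country,location,sex,age,politics,q1,q2\n"
        "r1,ES,rural,female,34,left,2,DK\n"
        "r2,ES,urban,male,55,centre,5,3\n"
        "r3,ES,rural,male,41,right,,4\n"
        "r4,SK,urban,female,29,missing,3,1\n"
    )
    path = tmp_path / "survey.csv"
    path.write_text(text, encoding="utf-8")
    schema = (
        osv.QuestionSpec("q1", 5, False),
        osv.QuestionSpec("q2", 5, True),
    )
    return path, schema


@pytest.fixture(scope="session")
def small_cfg():
    """A light sampler config for structural (non-statistical) tests."""
    return osv.McmcConfig(n_chains=3, n_iterations=1200, burn_in=600, seed=0)
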