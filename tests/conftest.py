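import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_survey():
    """The default-size synthetic survey (500 EAs x 5 households)."""
    from mistreat import SurveyConfig, generate_survey

    return generate_survey(SurveyConfig(seed=0))


@pytest.fixture(scope="session")
def small_survey():
    """A small survey for fast pipeline checks."""
    from mistreat import SurveyConfig, generate_survey

    return generate_survey(SurveyConfig(n_ea=80, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
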