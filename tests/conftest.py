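import pytest

from perinatal_roi import ScenarioOptions, load_parameters, run_projection


@pytest.fixture(scope="session")
def defaults():
    """The built-in parameter book."""
    return load_parameters()


@pytest.fixture(scope="session")
def default_options():
    """The reference scenario: professionals at US$235/month, volunteers at
    US$40/month, 50/50 group/individual and clinic/community delivery."""
    return ScenarioOptions()


@pytest.fixture(scope="session")
def default_result(defaults, default_options):
    """Full five-year projection under the defaults."""
    return run_projection(defaults, default_options)
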