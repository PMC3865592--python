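import pytest

from splicevar.splice_predictor import default_models
from splicevar.synthetic_data import SCENARIO_NAMES, build_scenario


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def scenarios(tmp_path_factory):
    """All named scenarios, built once per session."""
    root = tmp_path_factory.mktemp("scenarios")
    return {name: build_scenario(name, root, seed=1) for name in SCENARIO_NAMES}


@pytest.fixture(scope="session")
def gnaq(scenarios):
    return scenarios["gnaq_skip"]


@pytest.fixture(scope="session")
def hook1(scenarios):
    return scenarios["hook1_retention"]
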