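import pytest
from hypothesis import HealthCheck, settings

from lapassess import Assessor, default_config
from lapassess.config import build_variable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def assessor(cfg):
    return Assessor.from_config(cfg)


@pytest.fixture(scope="session")
def dist_var(cfg):
    return build_variable(cfg.variables["distance"])


@pytest.fixture(scope="session")
def height_var(cfg):
    return build_variable(cfg.variables["height"])


@pytest.fixture(scope="session")
def output_var(cfg):
    return build_variable(cfg.variables["hand_score"])
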