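import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pracopt.core_data import paper_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture():
    """The packaged 29-run extraction dataset with model predictions."""
    return paper_dataset()


@pytest.fixture(scope="session")
def design(fixture):
    return fixture.design


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
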