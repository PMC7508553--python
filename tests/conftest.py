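import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoselect import get_preset, simulate_lineages

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt():
    return get_preset("wt_live")


@pytest.fixture(scope="session")
def lineage_table(wt):
    return simulate_lineages(30, wt, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
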