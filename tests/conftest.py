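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

from frnkit.design import generate_schedule
from frnkit.layout import load_default_layout, scalp_adjacency


@pytest.fixture(scope="session")
def layout():
    return load_default_layout()


@pytest.fixture(scope="session")
def adjacency(layout):
    return scalp_adjacency(layout)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(5, 40, 0.2, seed=123)


@pytest.fixture(scope="session")
def tiny_schedule():
    return generate_schedule(1, 4, 0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
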