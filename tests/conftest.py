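import numpy as np
import pytest

from propellerevo.substmodel import get_model


@pytest.fixture(scope="session")
def jtt():
    return get_model("jtt")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family():
    """A compact simulated propeller family reused across modules."""
    from propellerevo.synthetic import simulate_family
    return simulate_family(n_propellers=5, age_spread=(0.1, 0.8), seed=101)
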