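import numpy as np
import pytest

from senflux.synthdata import (
    SyntheticSpec,
    chain_network,
    make_toy_network,
    simulate_expression,
    toy_kinetics,
    toy_medium,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def toy(spec):
    """(model, truth) for the default toy senescence network."""
    return make_toy_network(spec)


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def kinetics(toy_model):
    return toy_kinetics(toy_model)


@pytest.fixture(scope="session")
def medium():
    return toy_medium()


@pytest.fixture(scope="session")
def cc_profiles(toy, spec):
    """Default case–control expression profiles (5 studies, 5v5)."""
    model, truth = toy
    return simulate_expression(model, truth, spec, "case_control", seed=1)


@pytest.fixture(scope="session")
def ts_profiles(toy, spec):
    """Default time-series expression profiles (9 passages x 2)."""
    model, truth = toy
    return simulate_expression(model, truth, spec, "timeseries", seed=2)


@pytest.fixture
def chain():
    return chain_network()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
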