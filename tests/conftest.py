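import numpy as np
import pytest

from hemidiff.simulate import SimConfig, generate_dataset, simulation_forward_model


@pytest.fixture(scope="session")
def forward_model():
    """Montage, source grid, leadfield and scouts at default geometry."""
    return simulation_forward_model(SimConfig())


@pytest.fixture(scope="session")
def montage(forward_model):
    return forward_model[0]


@pytest.fixture(scope="session")
def source_space(forward_model):
    return forward_model[1]


@pytest.fixture(scope="session")
def leadfield(forward_model):
    return forward_model[2]


@pytest.fixture(scope="session")
def scouts_and_pairing(forward_model):
    return forward_model[3], forward_model[4]


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small simulated dataset (2 trials/class) for plumbing tests."""
    return generate_dataset(SimConfig(trials_per_class=2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
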