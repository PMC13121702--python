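import numpy as np
import pytest

from africo.reservoir import ESNModel, ReservoirInitSpec, make_reservoir


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_state_model(rng):
    """5-neuron state-feedback ESN with tanh activation."""
    W = make_reservoir(ReservoirInitSpec(N=5, seed=3))
    return ESNModel(
        W=W,
        W_in=rng.uniform(-1, 1, (5, 1)),
        W_fb=rng.uniform(-0.1, 0.1, (1, 5)),
        activation="tanh",
        feedback_mode="state",
    )


@pytest.fixture
def small_linear_model(rng):
    """5-neuron state-feedback ESN with identity activation."""
    W = make_reservoir(ReservoirInitSpec(N=5, seed=4))
    return ESNModel(
        W=W,
        W_in=rng.uniform(-1, 1, (5, 1)),
        W_fb=rng.uniform(-0.1, 0.1, (1, 5)),
        activation="identity",
        feedback_mode="state",
    )
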