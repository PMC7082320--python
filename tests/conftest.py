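import numpy as np
import pytest

from stdfa import NeuronParams, RateTaskSpec


@pytest.fixture
def params():
    """Default power-of-2 neuron parameters (tau_m=16, tau_s=4, nu=1)."""
    return NeuronParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task():
    """Tiny synthetic 3-class rate task for fast end-to-end tests."""
    return RateTaskSpec(n_classes=3, n_inputs=12, T=50, n_per_class=4, seed=7)


def random_train(rng, T, rate):
    """Random Bernoulli spike train as a SpikeTrain."""
    from stdfa import SpikeTrain

    return SpikeTrain.from_dense(rng.random(T) < rate)
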