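import numpy as np
import pytest

import bayeshead as bh

SMALL_SHAPE = (16, 16, 16)


@pytest.fixture(scope="session")
def small_dataset():
    """Separable cohort at desk scale: strong effect, low noise, no ambiguity."""
    cfg = bh.SynthConfig(
        n_subjects=40,
        shape=SMALL_SHAPE,
        effect_size=0.5,
        noise_sd=0.02,
        ambiguous_fraction=0.0,
        seed=11,
    )
    return bh.split_dataset(bh.generate_dataset(cfg), 0.8, seed=11)


@pytest.fixture(scope="session")
def small_trained(small_dataset):
    """A network trained on the separable cohort; shared across tests."""
    spec = bh.NetworkSpec(input_shape=SMALL_SHAPE, block_channels=(4, 8, 16))
    net = bh.build_network(spec, seed=11)
    return bh.train(net, small_dataset, bh.TrainConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_net():
    """Small untrained network for shape/gradient contracts."""
    spec = bh.NetworkSpec(input_shape=(8, 8, 8), block_channels=(2, 3, 4))
    return bh.build_network(spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
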