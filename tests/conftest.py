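import numpy as np
import pytest

from socialstate import SynthConfig, generate_session


@pytest.fixture(scope="session")
def strong_session():
    """Small population with strongly tuned neurons and ground truth."""
    cfg = SynthConfig(n_neurons=60, seed=11)
    traces, timeline, truth = generate_session(cfg)
    return cfg, traces, timeline, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
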