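import numpy as np
import pytest

import reactnorm as rn


@pytest.fixture(scope="session")
def small_dataset() -> rn.SynthDataset:
    """A small but complete trial network shared across read-only tests."""
    config = rn.SynthConfig(
        n_lines=20,
        n_environments=8,
        n_replicates=2,
        n_markers=120,
        n_ecs=8,
        seed=7,
    )
    return rn.simulate(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
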