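import numpy as np
import pytest

from spongetrace import simulate as sim
from spongetrace.constants import DEFAULT_REGISTRY


@pytest.fixture(scope="session")
def registry():
    return DEFAULT_REGISTRY


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic experiment (noise on)."""
    return sim.simulate(sim.default_config(seed=101))


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free synthetic experiment: measurements equal latent truth."""
    return sim.simulate(sim.default_config(seed=202).without_noise())


@pytest.fixture()
def rng():
    return np.random.default_rng(9157)
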