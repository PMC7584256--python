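import numpy as np
import pytest

from mltve.simulate import Sim1Config, Sim2Config, gen_sim1, gen_sim2


@pytest.fixture(scope="session")
def sim1_data():
    """One study-1 dataset at defaults (600 records, 30 groups of 20)."""
    return gen_sim1(Sim1Config(seed=20240601))


@pytest.fixture(scope="session")
def sim2_data():
    """One study-2 dataset at defaults (nonlinear third-variable model)."""
    return gen_sim2(Sim2Config(seed=20240602))


@pytest.fixture
def rng():
    return np.random.default_rng(991)
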