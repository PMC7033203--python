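import numpy as np
import pytest

from triptofunnel.config import SimulationConfig
from triptofunnel.synthetic import generate_all


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted synthetic dataset, generated once per session."""
    return generate_all(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
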