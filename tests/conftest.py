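import numpy as np
import pytest

from phaseflow.synthetic import SimulationConfig, generate_dataset

#: Duration scale for desk-scale test datasets (~2 min tracks instead of
#: ~45 min); track structure is unchanged.
SHORT = 0.05


@pytest.fixture(scope="session")
def small_dataset():
    """Twenty short synthetic videos under the default emission noise."""
    return generate_dataset(SimulationConfig(n_videos=20, seed=11).scaled(SHORT))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
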