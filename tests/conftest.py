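import numpy as np
import pytest

from canopy2sat import generate_dataset, load_sensor, simulate_sensor_table
from canopy2sat.synth import low_noise_params


@pytest.fixture(scope="session")
def ngs_library():
    """Low-noise 100-sample NGS library, seed 42."""
    return generate_dataset("NGS", 100, 42, params=low_noise_params("NGS"))


@pytest.fixture(scope="session")
def sentinel2_table(ngs_library):
    return simulate_sensor_table(ngs_library, load_sensor("sentinel2"))


@pytest.fixture(scope="session")
def landsat8_table(ngs_library):
    return simulate_sensor_table(ngs_library, load_sensor("landsat8"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
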