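import numpy as np
import pytest

from ampmap.formats import PipelineConfig
from ampmap.synthetic_data import SimConfig, simulate_reference


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def reference(sim_cfg):
    return simulate_reference(sim_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
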