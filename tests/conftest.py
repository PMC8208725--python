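import numpy as np
import pytest

from strainwise.config import PipelineConfig, load_config
from strainwise import simulate as sim


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return load_config()


@pytest.fixture(scope="session")
def tiny_ds() -> sim.SyntheticDataset:
    """Small noisy dataset shared by unit tests."""
    return sim.generate(sim.GeneratorParams(n_elements=60, n_genes=20, seed=5))


@pytest.fixture(scope="session")
def clean_ds() -> sim.SyntheticDataset:
    """Noise-free dataset: signals equal the activity-model means exactly."""
    return sim.generate(sim.GeneratorParams(n_elements=80, n_genes=20, seed=6,
                                            noise_dispersion=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
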