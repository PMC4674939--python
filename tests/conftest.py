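import numpy as np
import pytest
from hypothesis import settings

from polymethyl.config import SimulationConfig, Thresholds
from polymethyl.pipeline import run_pipeline, simulate_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_contigs=6, contig_length=1500, depth=30, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_pipeline(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
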