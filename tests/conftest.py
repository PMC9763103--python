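import numpy as np
import pytest

from founderscan.fixtures import load_fixture_tables, table3_pedigree
from founderscan.pipeline import PipelineParams, run_full, simulate_dataset
from founderscan.simulate import SimulationConfig


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def study_pedigree(tables):
    return table3_pedigree(tables)


@pytest.fixture(scope="session")
def dataset_p1():
    """Full-penetrance replicate of the default scenario (seed 7)."""
    cfg = SimulationConfig(penetrance=1.0, phenocopy_rate=0.0)
    return simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def dataset_clean():
    """Error-free replicate (no allele errors) for exact-truth checks."""
    cfg = SimulationConfig(penetrance=1.0, phenocopy_rate=0.0, allele_error_rate=0.0)
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def result_p1(dataset_p1):
    return run_full(dataset_p1, PipelineParams())


@pytest.fixture(scope="session")
def result_clean(dataset_clean):
    return run_full(dataset_clean, PipelineParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
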