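import numpy as np
import pytest

from svoconform import synth
from svoconform.task_design import generate_allocation_set, partition_subsets


@pytest.fixture(scope="session")
def allocation_set():
    return generate_allocation_set()


@pytest.fixture(scope="session")
def subsets(allocation_set):
    return partition_subsets(allocation_set)


@pytest.fixture(scope="session")
def design():
    return synth.build_design(0)


@pytest.fixture(scope="session")
def small_population(design):
    cfg = synth.PopulationConfig(
        n_per_condition={c: 5 for c in synth.CONDITIONS},
        trials_per_phase=60, seed=3)
    return synth.sample_population(cfg, design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
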