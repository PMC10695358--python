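import numpy as np
import pytest

from sstlearn import (RunConfig, RPEModelParams, compute_signals,
                      simulate_cohort, simulate_run)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()

@pytest.fixture(scope="session")
def one_run(default_config):
    return simulate_run("sub-001", 1, default_config, seed=42)


@pytest.fixture(scope="session")
def one_run_signals(one_run):
    return compute_signals(one_run, RPEModelParams(), rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """12 subjects x 2 waves; enough structure for QC/pipeline tests."""
    return simulate_cohort(12, (1, 2), default_config, seed=7)
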