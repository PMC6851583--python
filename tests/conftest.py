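import numpy as np
import pytest

from picovir import simulate as sim


@pytest.fixture(scope="session")
def default_result():
    """One full default-condition experiment (seed 1), flow events included."""
    return sim.run_experiment(sim.SimConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_result():
    """Deterministic trajectory: no measurement noise, no burst variability."""
    cfg = sim.SimConfig(seed=1, burst_cv=0.0, noise_cv_counts=0.0, n_replicates=1)
    return sim.run_experiment(cfg, emit_flow=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20190513)
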