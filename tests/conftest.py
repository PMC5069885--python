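import pytest

from tripkit import SimConfig, run_pipeline, simulate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """One full default-scale simulated experiment (1093 reporters)."""
    return simulate_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_sim):
    """The default experiment analyzed end to end."""
    return run_pipeline(default_sim, seed=1)


@pytest.fixture()
def small_config():
    """A fast configuration for smoke tests (structure, not statistics)."""
    return SimConfig(seed=7, n_integrations=40, n_spike_barcodes=20, n_decoys=1)
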