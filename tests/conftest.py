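import numpy as np
import pytest

from semtrf import simulate as sim


@pytest.fixture(scope="session")
def toy_lm():
    """5-gram model on the packaged corpus (shared across the suite)."""
    return sim.train_toy_lm()


@pytest.fixture(scope="session")
def bigram_lm():
    return sim.train_toy_lm(order=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort(toy_lm):
    """Tiny two-group cohort reused by pipeline-level tests."""
    cfg = sim.SimulationConfig(
        seed=11,
        n_per_group=2,
        channels=("Fz", "Cz", "CPz", "Pz"),
        rate=64.0,
        duration_s=80.0,
        trial_s=20.0,
        altered_interval_s=15.0,
        snr_db=0.0,
    )
    return sim.simulate_cohort(cfg, lm=toy_lm)
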