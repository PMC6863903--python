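import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainpop import simdata

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_community():
    """Two-clade community with error-free counts for truth-based checks."""
    cfg = simdata.SimulationConfig(
        n_strains=6,
        clade_sizes=(3, 3),
        d_between=80,
        d_within=12,
        genome_length=9000,
        n_genes=15,
        n_samples=8,
        coverage=100,
        seq_error=0.0,
        invariant_snv_rate=2e-3,
        seed=11,
    )
    truth = simdata.simulate_strains(cfg)
    counts = simdata.simulate_counts(truth, cfg)
    return cfg, truth, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
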