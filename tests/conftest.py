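import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_community():
    """A coupled 8-user community reused by read-only tests."""
    from affsync.synthetic_data import SimulationConfig, simulate_community

    cfg = SimulationConfig(
        n_users=8, n_interactions_range=(100, 160), coupling=0.8, seed=11
    )
    return simulate_community(cfg)
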