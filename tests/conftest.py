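import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    from efcascade.simulate import simulate_study

    return simulate_study(n_genes=120, seed=7, n_single_edges=12, n_synergy=2,
                          n_bound_only_per_tf=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
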