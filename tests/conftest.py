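import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def orthogonal_templates():
    """Four orthonormal zero-mean topographies over 16 channels."""
    from mstate import make_templates

    return make_templates(16, 4, seed=42)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by several slow-path tests."""
    from mstate import SimConfig, generate_study

    cfg = SimConfig(seed=7, n_channels=20, n_subjects=4,
                    n_trials_per_condition=2, snr=8.0)
    return generate_study(cfg)
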