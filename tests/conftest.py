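import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study_case():
    """One scaled simulated Shepp-Logan acquisition, shared read-only."""
    from deringer.experiments import build_study_case

    return build_study_case("shepp_logan", det_width=412, n_angles=200, seed=1)
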