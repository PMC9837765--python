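import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def low_contrast_patient():
    """One seeded low-contrast synthetic patient, shared across tests."""
    from raclahe.phantom import generate_patient, low_contrast_spec

    return generate_patient(low_contrast_spec(slices_per_patient=4), patient_seed=42)
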