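import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from irdprio.cohort import build_reference_fixture


@pytest.fixture(scope="session")
def reference():
    """Reconstructed study family without decoys (6 variants, 9 WGS samples)."""
    return build_reference_fixture(n_decoys_per_class=0)


@pytest.fixture(scope="session")
def reference_with_decoys():
    """Reconstructed study family salted with two decoys per filter class."""
    return build_reference_fixture(n_decoys_per_class=2)
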