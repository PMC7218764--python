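import pytest
from hypothesis import HealthCheck, settings

from rhdcea import ScreeningCEA, generate_toy_bundle, reference_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return reference_bundle()


@pytest.fixture(scope="session")
def toy():
    return generate_toy_bundle()


@pytest.fixture(scope="session")
def model(bundle):
    return ScreeningCEA(bundle)
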