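import pytest
from hypothesis import HealthCheck, settings

from loraln import build_index, make_reference

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_20k():
    return make_reference(20_000, rng_seed=20260929)


@pytest.fixture(scope="session")
def index_20k(ref_20k):
    return build_index(ref_20k)


@pytest.fixture(scope="session")
def ref_1mb():
    return make_reference(1_000_000, rng_seed=20260929)


@pytest.fixture(scope="session")
def index_1mb(ref_1mb):
    return build_index(ref_1mb)
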