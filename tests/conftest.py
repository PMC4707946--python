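import pytest

from kidsim import reference
from kidsim.population import TownProfile


@pytest.fixture(scope="session")
def bundle():
    return reference.generate_reference_bundle(seed=1)


@pytest.fixture(scope="session")
def profile_a(bundle):
    return TownProfile.from_bundle("A", bundle)


@pytest.fixture(scope="session")
def profile_b(bundle):
    return TownProfile.from_bundle("B", bundle)


@pytest.fixture(scope="session")
def profile_c(bundle):
    return TownProfile.from_bundle("C", bundle)
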