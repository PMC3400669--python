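import pytest

from snpmeta import GeneticModel, bundled_fixture


@pytest.fixture(scope="session")
def fixture_collection():
    return bundled_fixture()


@pytest.fixture(scope="session")
def all_models():
    return list(GeneticModel)
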