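import pytest

from unhs.fixtures import FixtureConfig, generate_catalogs, generate_mock_registry


@pytest.fixture(scope="session")
def mock_registry():
    return generate_mock_registry(FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def study_shape_fixture():
    """Five facilities, 100 services, Table-1-shaped disharmony rates."""
    config = FixtureConfig(seed=11)
    registry = generate_mock_registry(config)
    catalogs, truth = generate_catalogs(config, registry)
    return config, registry, catalogs, truth
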