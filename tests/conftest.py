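import pytest
from hypothesis import settings

from idpsitemap.disorder import RandomCoilTable
from idpsitemap.synth import GeneratorConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rc_table() -> RandomCoilTable:
    return RandomCoilTable.bundled()


@pytest.fixture
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)
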