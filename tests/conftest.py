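import pytest
from hypothesis import settings

from quake_biogeo import SeawaterReference

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def seawater():
    return SeawaterReference.default()
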