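import pytest

from cassnet.synth import toy_fixtures


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture(scope="session")
def two_k4(toys):
    return toys["two_k4_bridge"]
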