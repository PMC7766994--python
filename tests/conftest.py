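import pytest

import coldkin as ck


@pytest.fixture(scope="session")
def bream():
    return ck.make_preset("sea_bream")


@pytest.fixture(scope="session")
def bass():
    return ck.make_preset("sea_bass")


@pytest.fixture(scope="session")
def tuna():
    return ck.make_preset("tuna")


@pytest.fixture(scope="session")
def bream_tvbn_model(bream):
    return bream.indices["TVBN"].arrhenius


@pytest.fixture(scope="session")
def bream_sensory(bream):
    ip = bream.indices["overall_acceptability"]
    return ip.spec(), ip.arrhenius
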