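import pytest

from thrombonet import fixture_network


@pytest.fixture
def path3():
    return fixture_network("path3")


@pytest.fixture
def path4():
    return fixture_network("path4")


@pytest.fixture
def star5_out():
    return fixture_network("star5_out")


@pytest.fixture
def cycle10():
    return fixture_network("cycle10")


@pytest.fixture
def clique4():
    return fixture_network("clique4")


@pytest.fixture
def twin_cliques():
    return fixture_network("twin_cliques")
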