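import pytest

from foodwebtopo import fixture_webs


@pytest.fixture(scope="session")
def fixtures():
    return fixture_webs()


@pytest.fixture(scope="session")
def star_10(fixtures):
    return fixtures["star_10"]


@pytest.fixture(scope="session")
def chain_3(fixtures):
    return fixtures["chain_3"]


@pytest.fixture(scope="session")
def complete_10(fixtures):
    return fixtures["complete_10"]


@pytest.fixture(scope="session")
def double_star_12(fixtures):
    return fixtures["double_star_12"]
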