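import pytest

from molforge import fixtures, perceive_bonds


@pytest.fixture
def methane():
    return fixtures.make("methane")


@pytest.fixture
def ethane_staggered():
    return fixtures.make("ethane_staggered")


@pytest.fixture
def ethane_eclipsed():
    return fixtures.make("ethane_eclipsed")


@pytest.fixture
def benzene():
    return fixtures.make("benzene")


@pytest.fixture
def butanol():
    return fixtures.make("s_2_butanol")


@pytest.fixture
def methylcyclohexane():
    return fixtures.make("methylcyclohexane_skeleton")


@pytest.fixture
def perceived_benzene(benzene):
    return perceive_bonds(benzene)
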