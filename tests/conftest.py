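import pytest

from critfrag import build_graph, load_fixture
from critfrag.fixtures import FIXTURE_NAMES


@pytest.fixture(scope="session")
def mechanisms():
    return {name: load_fixture(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def substrate_inhibition(mechanisms):
    return mechanisms["reversible_substrate_inhibition"]


@pytest.fixture(scope="session")
def substrate_inhibition_graph(substrate_inhibition):
    return build_graph(substrate_inhibition)


@pytest.fixture(scope="session")
def glycolysis(mechanisms):
    return mechanisms["glycolysis_gluconeogenesis"]
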