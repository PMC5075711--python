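import pytest

from thomasnet import casestudy as cs
from thomasnet.brn import build_state_graph


@pytest.fixture(scope="session")
def case_network():
    """The five-entity ER-alpha network with its selected parameters."""
    return cs.load_reference_network()


@pytest.fixture(scope="session")
def case_graph(case_network):
    brn, k = case_network
    return build_state_graph(brn, k)


@pytest.fixture(scope="session")
def reference_partition():
    return cs.load_reference_partition()


@pytest.fixture(scope="session")
def discrete_report():
    return cs.run_discrete_analysis()


@pytest.fixture(scope="session")
def continuous_report():
    return cs.run_continuous_analysis()
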