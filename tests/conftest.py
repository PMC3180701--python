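import pytest

from flavnet.network import Compound, MetabolicNetwork, Reaction
from flavnet.synthetic import make_mini_abp_fixture


@pytest.fixture(scope="session")
def mini_abp():
    """(network, planted answer, class map) for the mini pigment pathway."""
    return make_mini_abp_fixture()


@pytest.fixture()
def diamond():
    """Two parallel routes between one source and one sink."""
    net = MetabolicNetwork(name="diamond")
    net.add_compound(Compound("SRC", role="external"))
    net.add_compound(Compound("A"))
    net.add_compound(Compound("B"))
    net.add_compound(Compound("SNK", role="external"))
    net.add_reaction(Reaction("r1", {"SRC": -1, "A": 1}))
    net.add_reaction(Reaction("r2", {"A": -1, "B": 1}))
    net.add_reaction(Reaction("r3", {"A": -1, "B": 1}))
    net.add_reaction(Reaction("r4", {"B": -1, "SNK": 1}))
    return net


@pytest.fixture()
def chain3():
    net = MetabolicNetwork(name="chain")
    net.add_compound(Compound("A", role="external"))
    net.add_compound(Compound("B"))
    net.add_compound(Compound("C", role="external"))
    net.add_reaction(Reaction("r1", {"A": -1, "B": 1}))
    net.add_reaction(Reaction("r2", {"B": -1, "C": 1}))
    return net
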