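import pytest

from sarconet import synthesize_rules, toy_map
from sarconet.network_core import Element, MolecularNetwork, Reaction, build_network


@pytest.fixture(scope="session")
def toy_net():
    return toy_map()


@pytest.fixture(scope="session")
def toy_model(toy_net):
    return synthesize_rules(toy_net)


def make_flow_network(edges, extra_elements=()):
    """Build a network from (source, sign, target) triples via activity-flow
    reactions; elements are created automatically."""
    ids = {e for s, _, t in edges for e in (s, t)} | set(extra_elements)
    elements = [Element(i) for i in sorted(ids)]
    reactions = [
        Reaction(f"r{k}", "activity_flow", (s,), (t,), sign=sign)
        for k, (s, sign, t) in enumerate(edges)
    ]
    return build_network(elements, reactions)


@pytest.fixture
def flow_network():
    return make_flow_network
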