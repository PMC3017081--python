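import networkx as nx
import pytest

from pathexpand import (
    PlantedNetworkSpec,
    emit_incomplete_gmt,
    generate_planted_network,
)


@pytest.fixture(scope="session")
def planted():
    """Default planted-community benchmark (5 x 20 communities, 100 background)."""
    spec = PlantedNetworkSpec(seed=0)
    network, truth = generate_planted_network(spec)
    sets, truth = emit_incomplete_gmt(truth, 0.1, seed=0)
    return network, sets, truth


@pytest.fixture(scope="session")
def planted_full():
    """Same network with the complete (nothing hidden) community gene sets."""
    spec = PlantedNetworkSpec(seed=0)
    network, truth = generate_planted_network(spec)
    sets, truth = emit_incomplete_gmt(truth, 0.0, seed=0)
    return network, sets, truth


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edge("a", "b")
    g.add_edge("b", "c")
    return g


@pytest.fixture
def star4():
    """Star with centre 'hub' and 3 leaves."""
    g = nx.Graph()
    g.add_edges_from([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
    return g
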