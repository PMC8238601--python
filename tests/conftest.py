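import networkx as nx
import pytest

from netpharm import SyntheticConfig, TypedNetwork, make_planted_fixture
from netpharm.networks import REL_PPI, ROLE_TARGET


def typed_from_nx(g: nx.Graph, role: str = ROLE_TARGET) -> TypedNetwork:
    """Wrap a plain networkx graph as an all-protein TypedNetwork."""
    net = TypedNetwork()
    for v in g.nodes:
        net.add_node(str(v), role)
    for u, v in g.edges:
        net.add_edge(str(u), str(v), REL_PPI)
    return net


@pytest.fixture
def path3() -> TypedNetwork:
    return typed_from_nx(nx.path_graph(["a", "b", "c"]))


@pytest.fixture(scope="session")
def planted():
    return make_planted_fixture(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def planted_networks(planted):
    disease, ct, ctp = planted.assemble()
    return {"disease": disease, "ct": ct, "ctp": ctp}
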