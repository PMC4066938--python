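import random

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

TOY_EDGES = [
    ("v1", "v2"), ("v1", "v3"), ("v2", "v3"), ("v1", "v4"),
    ("v4", "v5"), ("v4", "v6"), ("v5", "v6"), ("v3", "v6"),
]


@pytest.fixture
def toy_graph() -> nx.Graph:
    """Six-node, eight-edge network with two planted triangles
    {v1,v2,v3} and {v4,v5,v6} joined by the v1-v4 and v3-v6 edges."""
    G = nx.Graph(weighted=False)
    G.add_edges_from(TOY_EDGES)
    return G


def random_graph(rng: random.Random, n: int, p: float = 0.4) -> nx.Graph:
    """Erdős–Rényi-style graph on string nodes n0..n{n-1}."""
    G = nx.Graph(weighted=False)
    names = [f"n{i}" for i in range(n)]
    G.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(names[i], names[j])
    return G


def random_membership(rng: random.Random, n: int, k_max: int = 5) -> dict:
    """Random node → community-id map on nodes n0..n{n-1}."""
    k = rng.randint(1, k_max)
    return {f"n{i}": rng.randrange(k) for i in range(n)}
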