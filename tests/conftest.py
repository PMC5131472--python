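import networkx as nx
import numpy as np
import pytest

from netweights import toy_fig1


def random_weighted_graph(seed: int, n: int | None = None, p: float | None = None) -> nx.Graph:
    """A seeded random graph with positive random weights and string labels."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(5, 26))
    if p is None:
        p = float(rng.uniform(0.15, 0.5))
    base = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    G = nx.Graph()
    G.add_nodes_from(f"v{i:02d}" for i in base.nodes())
    for u, v in base.edges():
        G.add_edge(f"v{u:02d}", f"v{v:02d}", weight=float(rng.uniform(0.05, 1.0)))
    return G


def unit_weight(G: nx.Graph) -> nx.Graph:
    H = G.copy()
    for _, _, data in H.edges(data=True):
        data["weight"] = 1.0
    return H


@pytest.fixture
def fig1() -> nx.Graph:
    return toy_fig1(weighted=False)


@pytest.fixture
def fig1_weighted() -> nx.Graph:
    return toy_fig1(weighted=True)
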