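import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wppi import ComplexSet


@pytest.fixture
def unit_triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    return g


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from(
        [
            ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
            ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
        ]
    )
    return g


def random_complex_set(
    rng: np.random.Generator, n: int, label: str = "", disjoint: bool = False
) -> ComplexSet:
    """Random non-empty complex set over a shared protein universe.

    With ``disjoint`` the complexes partition distinct proteins (the regime
    where a self-comparison scores 1 on every metric); otherwise complexes
    may overlap.
    """
    universe = [f"g{i}" for i in range(80)]
    complexes = []
    if disjoint:
        pool = list(rng.permutation(universe))
        for _ in range(n):
            size = int(rng.integers(2, 8))
            complexes.append(frozenset(pool[:size]))
            pool = pool[size:]
    else:
        for _ in range(n):
            size = int(rng.integers(2, 8))
            complexes.append(frozenset(rng.choice(universe, size=size, replace=False)))
    return ComplexSet(complexes=complexes, label=label)


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p: float) -> nx.Graph:
    """Erdos-Renyi graph with uniform [0, 1] edge weights."""
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.random()))
    return g
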