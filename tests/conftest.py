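import numpy as np
import pytest

from vectorops.road_network import RoadNetwork, build_network


@pytest.fixture
def unit_square():
    """Unit square A-B-C-D (1 km sides) plus a 1.5 km diagonal A-C."""
    nodes = {
        "A": (0.0, 0.0),
        "B": (1000.0, 0.0),
        "C": (1000.0, 1000.0),
        "D": (0.0, 1000.0),
    }
    edges = [
        ("A", "B"),
        ("B", "C"),
        ("C", "D"),
        ("D", "A"),
        ("A", "C", 1500.0),
    ]
    return build_network(nodes, edges)


@pytest.fixture
def line_graph():
    """Line 0-1-2-3-4 with unit (1 km) edges."""
    nodes = {i: (i * 1000.0, 0.0) for i in range(5)}
    edges = [(i, i + 1) for i in range(4)]
    return build_network(nodes, edges)


def random_connected_network(seed: int, max_nodes: int = 30) -> RoadNetwork:
    """Random connected graph: random spanning tree + random extra edges,
    random positive edge lengths (decoupled from coordinates)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    nodes = {f"v{i}": (float(rng.uniform(0, 5000)), float(rng.uniform(0, 5000)))
             for i in range(n)}
    ids = list(nodes)
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((ids[i], ids[j], float(rng.uniform(10, 3000))))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j and not any(
            {ids[i], ids[j]} == {u, v} for u, v, _ in edges
        ):
            edges.append((ids[int(i)], ids[int(j)], float(rng.uniform(10, 3000))))
    return build_network(nodes, edges)
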