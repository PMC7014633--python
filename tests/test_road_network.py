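import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vectorops.road_network import (
    NetworkStructureError,
    NetworkValidationError,
    SnapConfig,
    build_network,
    distance_matrix,
    read_network_csv,
    read_network_geojson,
    shortest_path,
    snap_point,
    snap_points,
    write_network_geojson,
)

from conftest import random_connected_network


def floyd_warshall(network):
    """Independent all-pairs oracle: plain triple-loop relaxation."""
    ids = sorted(network.graph.nodes(), key=str)
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in network.graph.edges(data=True):
        i, j = index[u], index[v]
        dist[i, j] = dist[j, i] = min(dist[i, j], data["length_km"])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return ids, index, dist


class TestBuildNetwork:
    def test_euclidean_length_default(self):
        net = build_network({"a": (0, 0), "b": (1000, 0)}, [("a", "b")])
        assert net.edge_length_km("a", "b") == pytest.approx(1.0)

    def test_unit_square_fixture_shape(self, unit_square):
        assert unit_square.n_nodes == 4
        assert unit_square.n_edges == 5
        assert unit_square.edge_length_km("A", "C") == pytest.approx(1.5)

    def test_dangling_endpoint_is_structural_error(self):
        with pytest.raises(NetworkStructureError):
            build_network({"a": (0, 0)}, [("a", "Z")])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(NetworkValidationError):
            build_network({"a": (0, 0), "b": (1, 0)}, [("a", "b", 0.0)])

    def test_dataframe_input_with_missing_lengths(self):
        nodes = pd.DataFrame({"node_id": ["a", "b"], "x": [0.0, 3000.0], "y": [0.0, 4000.0]})
        edges = pd.DataFrame({"from": ["a"], "to": ["b"], "length_m": [np.nan]})
        net = build_network(nodes, edges)
        assert net.edge_length_km("a", "b") == pytest.approx(5.0)

    def test_component_count(self, unit_square):
        assert unit_square.connected_component_count() == 1
        net = build_network({"a": (0, 0), "b": (1, 1), "c": (2, 2), "d": (3, 3)},
                            [("a", "b"), ("c", "d")])
        assert net.connected_component_count() == 2


class TestSnap:
    def test_projection_onto_edge(self):
        net = build_network({"a": (0, 0), "b": (1000, 0)}, [("a", "b")])
        res = snap_point(net, (400.0, 100.0))
        assert res.reachable
        assert res.offset_m == pytest.approx(100.0)
        assert net.position(res.attached_node_id) == pytest.approx((400.0, 0.0))
        # split lengths sum to the original
        assert (
            net.edge_length_km("a", res.attached_node_id)
            + net.edge_length_km(res.attached_node_id, "b")
        ) == pytest.approx(1.0)

    def test_snap_matches_dense_sampling_oracle(self, unit_square):
        point = (620.0, 260.0)
        # oracle: minimum distance over a dense sampling of all edge points
        best = math.inf
        for u, v in list(unit_square.graph.edges()):
            (ux, uy), (vx, vy) = unit_square.position(u), unit_square.position(v)
            for t in np.linspace(0, 1, 5001):
                d = math.dist(point, (ux + t * (vx - ux), uy + t * (vy - uy)))
                best = min(best, d)
        res = snap_point(unit_square.copy(), point)
        assert res.offset_m == pytest.approx(best, abs=0.01)

    def test_point_on_node_attaches_to_node(self, unit_square):
        res = snap_point(unit_square, (0.0, 0.0))
        assert res.attached_node_id == "A"
        assert res.offset_m == pytest.approx(0.0)

    def test_out_of_tolerance_flagged_and_graph_untouched(self):
        net = build_network({"a": (0, 0), "b": (1000, 0)}, [("a", "b")])
        res = snap_point(net, (500.0, 600.0), SnapConfig(tolerance_m=500))
        assert not res.reachable
        assert res.attached_node_id is None
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_empty_network_errors(self):
        net = build_network({}, [])
        with pytest.raises(NetworkValidationError):
            snap_point(net, (0.0, 0.0))

    def test_snapping_preserves_existing_distances(self):
        for seed in range(5):
            net = random_connected_network(seed, max_nodes=15)
            ids, index, before = floyd_warshall(net)
            rng = np.random.default_rng(seed + 100)
            points = {
                f"p{i}": (float(rng.uniform(0, 5000)), float(rng.uniform(0, 5000)))
                for i in range(4)
            }
            snap_points(net, points, SnapConfig(tolerance_m=1e6))
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    after = shortest_path(net, a, b)
                    if math.isinf(before[i, j]):
                        assert after is None
                    else:
                        assert after.length_km == pytest.approx(before[i, j], abs=1e-9)

    def test_batch_results_independent_of_point_order(self):
        pts = {"p1": (300.0, 40.0), "p2": (700.0, -30.0), "p3": (310.0, 55.0)}
        nets, results = [], []
        for order in (["p1", "p2", "p3"], ["p3", "p1", "p2"]):
            net = build_network({"a": (0, 0), "b": (1000, 0)}, [("a", "b")])
            results.append(snap_points(net, {k: pts[k] for k in order}))
            nets.append(net)
        for pid in pts:
            assert results[0][pid].offset_m == pytest.approx(results[1][pid].offset_m)
            assert results[0][pid].attached_node_id == results[1][pid].attached_node_id


class TestShortestPath:
    def test_diagonal_beats_two_sides(self, unit_square):
        route = shortest_path(unit_square, "A", "C")
        assert route.length_km == pytest.approx(1.5)
        assert route.node_sequence == ("A", "C")

    def test_origin_equals_destination(self, unit_square):
        route = shortest_path(unit_square, "B", "B")
        assert route.length_km == 0.0
        assert route.node_sequence == ("B",)

    def test_cross_component_returns_none(self):
        net = build_network({"a": (0, 0), "b": (1, 1), "c": (2, 2), "d": (3, 3)},
                            [("a", "b"), ("c", "d")])
        assert shortest_path(net, "a", "c") is None

    def test_lexicographic_tie_break(self):
        # two equal-length paths a->b->d and a->c->d: pick a,b,d
        net = build_network(
            {"a": (0, 0), "b": (1, 1), "c": (1, -1), "d": (2, 0)},
            [("a", "b", 500), ("b", "d", 500), ("a", "c", 500), ("c", "d", 500)],
        )
        route = shortest_path(net, "a", "d")
        assert route.node_sequence == ("a", "b", "d")

    def test_route_reversal_invariance(self):
        for seed in range(10):
            net = random_connected_network(seed)
            ids = sorted(net.graph.nodes(), key=str)
            rng = np.random.default_rng(seed)
            a, b = rng.choice(ids, size=2, replace=False)
            fwd, rev = shortest_path(net, a, b), shortest_path(net, b, a)
            assert fwd.length_km == pytest.approx(rev.length_km, abs=1e-9)

    def test_matches_floyd_warshall_oracle(self):
        for seed in range(20):
            net = random_connected_network(seed)
            ids, index, dist = floyd_warshall(net)
            rng = np.random.default_rng(seed + 1)
            for _ in range(10):
                a, b = rng.choice(ids, size=2)
                route = shortest_path(net, a, b)
                expected = dist[index[a], index[b]]
                if math.isinf(expected):
                    assert route is None
                else:
                    assert route.length_km == pytest.approx(expected, abs=1e-9)
                    # path is a real walk with consistent length
                    total = sum(
                        net.edge_length_km(u, v)
                        for u, v in zip(route.node_sequence, route.node_sequence[1:])
                    )
                    assert total == pytest.approx(route.length_km, abs=1e-9)


class TestDistanceMatrix:
    def test_single_pair_zero(self, line_graph):
        dm = distance_matrix(line_graph, [2], [2])
        assert dm.loc[2, 2] == 0.0

    def test_line_graph_rows(self, line_graph):
        dm = distance_matrix(line_graph, [0, 4], [0, 1, 2, 3, 4])
        assert list(dm.loc[0]) == pytest.approx([0, 1, 2, 3, 4])
        assert list(dm.loc[4]) == pytest.approx([4, 3, 2, 1, 0])

    def test_symmetric_when_square(self, unit_square):
        ids = sorted(unit_square.graph.nodes())
        dm = distance_matrix(unit_square, ids, ids)
        assert np.allclose(dm.to_numpy(), dm.to_numpy().T)

    def test_unknown_id_errors(self, line_graph):
        with pytest.raises(KeyError):
            distance_matrix(line_graph, [0], ["nope"])

    def test_unreachable_pairs_are_inf(self):
        net = build_network({"a": (0, 0), "b": (1, 1), "c": (2, 2), "d": (3, 3)},
                            [("a", "b"), ("c", "d")])
        dm = distance_matrix(net, ["a"], ["c"])
        assert math.isinf(dm.loc["a", "c"])

    def test_triangle_inequality(self):
        for seed in range(5):
            net = random_connected_network(seed, max_nodes=12)
            ids = sorted(net.graph.nodes(), key=str)
            dm = distance_matrix(net, ids, ids).to_numpy()
            finite = np.isfinite(dm)
            for i in range(len(ids)):
                for j in range(len(ids)):
                    for k in range(len(ids)):
                        if finite[i, k] and finite[k, j]:
                            assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-9


class TestIO:
    def test_geojson_roundtrip(self, unit_square, tmp_path):
        path = tmp_path / "net.geojson"
        write_network_geojson(unit_square, path)
        back = read_network_geojson(path)
        assert back.n_nodes == unit_square.n_nodes
        assert back.n_edges == unit_square.n_edges
        # distances survive the round trip (ids are renamed)
        dm = sorted(
            distance_matrix(back, sorted(back.graph.nodes()), sorted(back.graph.nodes()))
            .to_numpy().ravel()
        )
        ids = sorted(unit_square.graph.nodes())
        dm0 = sorted(distance_matrix(unit_square, ids, ids).to_numpy().ravel())
        assert dm == pytest.approx(dm0, abs=1e-9)

    def test_csv_reader(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("node_id,x,y\na,0,0\nb,1000,0\n")
        (tmp_path / "edges.csv").write_text("from,to,length_m\na,b,\n")
        net = read_network_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
        assert net.edge_length_km("a", "b") == pytest.approx(1.0)

    def test_geojson_chain_decomposition_with_declared_length(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[0, 0], [1000, 0], [1000, 1000]],
                    },
                    "properties": {"length_m": 3000.0},
                }
            ],
        }
        import json

        path = tmp_path / "chain.geojson"
        path.write_text(json.dumps(doc))
        net = read_network_geojson(path)
        assert net.n_nodes == 3 and net.n_edges == 2
        total = sum(d["length_km"] for _, _, d in net.graph.edges(data=True))
        assert total == pytest.approx(3.0)
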