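"""Road graph construction, point snapping, and shortest-path routing.

The road network is an undirected planar graph with a single uniform
impedance: driving distance in kilometres.  Node coordinates are planar
metres (a projected CRS is assumed); edge lengths are stored in km so
that every downstream quantity (service bins, fuel costs, p-median
objectives) is in the units of the reports.

Demand points and facilities rarely sit exactly on a road, so they are
*snapped*: attached to the globally nearest point on any edge, inserting
a virtual node at the perpendicular projection when that point falls in
the interior of an edge.  Snapping never changes any pre-existing
shortest-path distance.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

__all__ = [
    "NetworkStructureError",
    "NetworkValidationError",
    "RoadNetwork",
    "SnapConfig",
    "SnapResult",
    "Route",
    "build_network",
    "snap_point",
    "snap_points",
    "shortest_path",
    "distance_matrix",
    "read_network_geojson",
    "read_network_csv",
    "write_network_geojson",
    "write_routes_geojson",
]

NodeId = Hashable

# below this separation (metres along an edge) snapped points share a node,
# so no zero-length edge can ever be created
_MERGE_EPS_M = 1e-6


class NetworkStructureError(ValueError):
    """An edge references a node that does not exist."""


class NetworkValidationError(ValueError):
    """A network quantity violates its contract (e.g. nonpositive length)."""


@dataclass(frozen=True)
class SnapConfig:
    """Snap search tolerance; points farther than this from every edge
    are flagged unreachable and excluded downstream."""

    tolerance_m: float = 500.0

    def __post_init__(self) -> None:
        if not self.tolerance_m > 0:
            raise NetworkValidationError("tolerance_m must be > 0")


@dataclass(frozen=True)
class SnapResult:
    source_point_id: Hashable
    attached_node_id: NodeId | None
    offset_m: float
    reachable: bool


@dataclass(frozen=True)
class Route:
    """A shortest path between two graph nodes.

    ``node_sequence`` lists every traversed node, origin first;
    ``length_km`` is the sum of traversed edge lengths.
    """

    origin_node_id: NodeId
    destination_node_id: NodeId
    node_sequence: tuple[NodeId, ...]
    length_km: float


class RoadNetwork:
    """Undirected graph with ``pos`` (x, y metres) on nodes and strictly
    positive ``length_km`` on edges."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.validate()

    # -- construction ---------------------------------------------------

    def copy(self) -> "RoadNetwork":
        return RoadNetwork(self.graph.copy())

    def validate(self) -> None:
        for node, data in self.graph.nodes(data=True):
            pos = data.get("pos")
            if pos is None or len(pos) != 2:
                raise NetworkValidationError(f"node {node!r} has no planar position")
        for u, v, data in self.graph.edges(data=True):
            length = data.get("length_km")
            if length is None or not length > 0:
                raise NetworkValidationError(
                    f"edge ({u!r}, {v!r}) has nonpositive or missing length: {length!r}"
                )

    # -- basic queries --------------------------------------------------

    def __contains__(self, node: NodeId) -> bool:
        return node in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, node: NodeId) -> tuple[float, float]:
        return tuple(self.graph.nodes[node]["pos"])

    def edge_length_km(self, u: NodeId, v: NodeId) -> float:
        return self.graph.edges[u, v]["length_km"]

    def connected_component_count(self) -> int:
        return nx.number_connected_components(self.graph)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def coordinate_centroid(self) -> tuple[float, float]:
        xs, ys = zip(*(d["pos"] for _, d in self.graph.nodes(data=True)))
        return float(np.mean(xs)), float(np.mean(ys))


def build_network(
    node_table: pd.DataFrame | Mapping[NodeId, tuple[float, float]],
    edge_table: pd.DataFrame | Iterable[tuple],
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from node and edge tables.

    ``node_table`` is a DataFrame with columns ``node_id, x, y`` (metres)
    or a mapping ``node_id -> (x, y)``.  ``edge_table`` is a DataFrame
    with columns ``from, to`` and optional ``length_m``, or an iterable
    of ``(from, to)`` / ``(from, to, length_m)`` tuples.  Missing lengths
    are computed as planar Euclidean distance (metres -> km).

    Raises :class:`NetworkStructureError` for dangling edge endpoints and
    :class:`NetworkValidationError` for nonpositive lengths.
    """
    graph = nx.Graph()

    if isinstance(node_table, pd.DataFrame):
        node_iter = (
            (row["node_id"], (float(row["x"]), float(row["y"])))
            for _, row in node_table.iterrows()
        )
    else:
        node_iter = ((nid, (float(x), float(y))) for nid, (x, y) in node_table.items())
    for nid, pos in node_iter:
        graph.add_node(nid, pos=pos)

    if isinstance(edge_table, pd.DataFrame):
        records = edge_table.to_dict("records")
        edge_iter = [
            (r["from"], r["to"], r.get("length_m")) for r in records
        ]
    else:
        edge_iter = [tuple(e) + (None,) * (3 - len(tuple(e))) for e in edge_table]

    for u, v, length_m in edge_iter:
        for endpoint in (u, v):
            if endpoint not in graph:
                raise NetworkStructureError(
                    f"edge ({u!r}, {v!r}) references unknown node {endpoint!r}"
                )
        if length_m is None or (isinstance(length_m, float) and math.isnan(length_m)):
            length_m = math.dist(graph.nodes[u]["pos"], graph.nodes[v]["pos"])
        length_km = float(length_m) / 1000.0
        if not length_km > 0:
            raise NetworkValidationError(
                f"edge ({u!r}, {v!r}) has nonpositive length {length_m!r} m"
            )
        graph.add_edge(u, v, length_km=length_km)

    return RoadNetwork(graph)


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------


def snap_points(
    network: RoadNetwork,
    points: Mapping[Hashable, tuple[float, float]],
    config: SnapConfig = SnapConfig(),
) -> dict[Hashable, SnapResult]:
    """Snap many points onto the network, mutating it in place.

    Each point attaches to the globally nearest location on any edge
    (perpendicular projection clamped to the segment).  Interior
    attachments insert a virtual node named ``snap:<point_id>`` that
    splits the host edge into two edges whose lengths sum to the
    original.  Points whose straight-line offset exceeds the tolerance
    get ``reachable=False`` and leave the graph untouched.

    Projections are computed against the network as passed in, so the
    result is independent of point order.
    """
    if network.n_edges == 0:
        raise NetworkValidationError("cannot snap onto an empty network")

    edge_keys = sorted(
        ((u, v) for u, v in network.graph.edges()),
        key=lambda e: (str(e[0]), str(e[1])),
    )
    geoms = [
        LineString([network.position(u), network.position(v)]) for u, v in edge_keys
    ]
    tree = STRtree(geoms)

    results: dict[Hashable, SnapResult] = {}
    # host edge -> list of (metres along edge geometry, point_id, coordinate)
    pending: dict[tuple[NodeId, NodeId], list[tuple[float, Hashable, tuple]]] = {}

    for pid in points:
        pt = Point(points[pid])
        idx = int(tree.nearest(pt))
        line = geoms[idx]
        offset_m = float(line.distance(pt))
        if offset_m > config.tolerance_m:
            results[pid] = SnapResult(pid, None, offset_m, False)
            continue
        along_m = float(line.project(pt))
        u, v = edge_keys[idx]
        seg_m = line.length
        if along_m <= _MERGE_EPS_M:
            results[pid] = SnapResult(pid, u, offset_m, True)
        elif along_m >= seg_m - _MERGE_EPS_M:
            results[pid] = SnapResult(pid, v, offset_m, True)
        else:
            coord = line.interpolate(along_m)
            pending.setdefault((u, v), []).append((along_m, pid, (coord.x, coord.y)))

    for (u, v), hits in pending.items():
        hits.sort(key=lambda h: (h[0], str(h[1])))
        total_km = network.edge_length_km(u, v)
        seg_m = math.dist(network.position(u), network.position(v))
        network.graph.remove_edge(u, v)
        prev_node, prev_along = u, 0.0
        prev_vid = None
        for along_m, pid, coord in hits:
            if prev_vid is not None and along_m - prev_along <= _MERGE_EPS_M:
                # coincident with the previous snapped point: share its node
                offset = _point_offset(points[pid], network.position(prev_vid))
                results[pid] = SnapResult(pid, prev_vid, offset, True)
                continue
            vid = f"snap:{pid}"
            network.graph.add_node(vid, pos=coord)
            frac = (along_m - prev_along) / seg_m
            network.graph.add_edge(prev_node, vid, length_km=frac * total_km)
            results[pid] = SnapResult(pid, vid, _point_offset(points[pid], coord), True)
            prev_node, prev_along, prev_vid = vid, along_m, vid
        network.graph.add_edge(
            prev_node, v, length_km=(seg_m - prev_along) / seg_m * total_km
        )

    return results


def _point_offset(source: tuple[float, float], attached: tuple[float, float]) -> float:
    return math.dist(source, attached)


def snap_point(
    network: RoadNetwork,
    point: tuple[float, float],
    config: SnapConfig = SnapConfig(),
    point_id: Hashable = "point",
) -> SnapResult:
    """Snap a single point; see :func:`snap_points`."""
    return snap_points(network, {point_id: point}, config)[point_id]


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------


def _path_key(path: tuple[NodeId, ...]) -> tuple[str, ...]:
    return tuple(str(n) for n in path)


def shortest_path(
    network: RoadNetwork, origin: NodeId, destination: NodeId
) -> Route | None:
    """Minimum-length route by Dijkstra's algorithm.

    Ties in length are broken by the lexicographically smallest node
    sequence (node ids compared as strings), so results are
    reproducible bit-for-bit.  Returns ``None`` when the destination is
    in a different connected component.
    """
    graph = network.graph
    for node in (origin, destination):
        if node not in graph:
            raise KeyError(f"node {node!r} not in network")
    if origin == destination:
        return Route(origin, destination, (origin,), 0.0)

    best: dict[NodeId, tuple[float, tuple[str, ...]]] = {}
    start = (0.0, _path_key((origin,)), (origin,))
    heap = [start]
    while heap:
        dist, key, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (dist, key) > best[node]:
            continue
        if node == destination:
            return Route(origin, destination, path, dist)
        for nbr, data in sorted(
            graph[node].items(), key=lambda kv: str(kv[0])
        ):
            ndist = dist + data["length_km"]
            npath = path + (nbr,)
            nkey = key + (str(nbr),)
            if nbr not in best or (ndist, nkey) < best[nbr]:
                best[nbr] = (ndist, nkey)
                heapq.heappush(heap, (ndist, nkey, npath))
    return None


def distance_matrix(
    network: RoadNetwork,
    origins: Sequence[NodeId],
    destinations: Sequence[NodeId],
) -> pd.DataFrame:
    """All origin-destination shortest-path lengths (km) as a DataFrame.

    Unreachable pairs are ``inf``.  Unknown ids raise ``KeyError``.
    """
    graph = network.graph
    for node in list(origins) + list(destinations):
        if node not in graph:
            raise KeyError(f"node {node!r} not in network")
    rows = {}
    for origin in origins:
        lengths = nx.single_source_dijkstra_path_length(
            graph, origin, weight="length_km"
        )
        rows[origin] = [lengths.get(d, math.inf) for d in destinations]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(destinations))
    return out.loc[list(origins)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_network_geojson(path) -> RoadNetwork:
    """Read a GeoJSON FeatureCollection of LineString features.

    Each LineString's vertex chain is decomposed into edges between
    consecutive vertices; vertices shared between features (identical
    coordinates) become a single node.  An optional numeric property
    ``length_m`` gives the whole chain's length, distributed over the
    segments in proportion to their Euclidean lengths.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise NetworkValidationError("expected a GeoJSON FeatureCollection")

    coord_ids: dict[tuple[float, float], str] = {}
    nodes: dict[str, tuple[float, float]] = {}
    edges: list[tuple[str, str, float]] = []

    def node_for(coord) -> str:
        key = (round(float(coord[0]), 6), round(float(coord[1]), 6))
        if key not in coord_ids:
            nid = f"n{len(coord_ids)}"
            coord_ids[key] = nid
            nodes[nid] = key
        return coord_ids[key]

    for feature in doc.get("features", []):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "LineString":
            continue
        coords = geom["coordinates"]
        ids = [node_for(c) for c in coords]
        seg_m = [
            math.dist(coords[i], coords[i + 1]) for i in range(len(coords) - 1)
        ]
        total = sum(seg_m)
        declared = (feature.get("properties") or {}).get("length_m")
        for i in range(len(ids) - 1):
            length = seg_m[i]
            if declared is not None and total > 0:
                length = float(declared) * seg_m[i] / total
            edges.append((ids[i], ids[i + 1], length))

    return build_network(nodes, edges)


def read_network_csv(nodes_path, edges_path) -> RoadNetwork:
    """Read node/edge CSVs (``node_id,x,y`` and ``from,to[,length_m]``)."""
    node_table = pd.read_csv(nodes_path, dtype={"node_id": str})
    edge_table = pd.read_csv(edges_path, dtype={"from": str, "to": str})
    return build_network(node_table, edge_table)


def write_network_geojson(network: RoadNetwork, path) -> None:
    features = []
    for u, v in sorted(network.graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        list(network.position(u)),
                        list(network.position(v)),
                    ],
                },
                "properties": {
                    "from": str(u),
                    "to": str(v),
                    "length_m": network.edge_length_km(u, v) * 1000.0,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")


def write_routes_geojson(routes: Iterable[Route], network: RoadNetwork, path) -> None:
    """Write routes as GeoJSON LineStrings with origin/destination/length."""
    features = []
    for route in routes:
        coords = [list(network.position(n)) for n in route.node_sequence]
        if len(coords) == 1:  # degenerate origin==destination route
            coords = coords * 2
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "origin": str(route.origin_node_id),
                    "destination": str(route.destination_node_id),
                    "length_km": route.length_km,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")
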