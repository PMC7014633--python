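"""Synthetic city generator.

Emits a connected jittered-grid road network, neighborhood demand points
with the spatial gradients the analysis assumes (housing condition
worsening toward the periphery, dengue cases concentrated centrally,
right-skewed block populations), two central active hubs, and dispersed
candidate subcenters.  Everything is deterministic under a fixed seed,
and the outputs round-trip through the same readers the pipeline uses
for real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .census_attributes import Neighborhood, write_neighborhoods_csv
from .facilities import Facility, write_facilities_geojson
from .road_network import RoadNetwork, write_network_geojson

__all__ = ["CityConfig", "SyntheticCity", "generate_network",
           "generate_neighborhoods", "place_facilities", "generate_city",
           "write_city"]


@dataclass(frozen=True)
class CityConfig:
    """Generator knobs; defaults emulate a mid-sized coastal city with
    ~254 census blocks served from two central spray hubs."""

    rows: int = 24
    cols: int = 24
    spacing_m: float = 250.0
    jitter_m: float = 30.0
    edge_dropout: float = 0.05  # connectivity-preserving
    n_neighborhoods: int = 254
    pop_mu_log: float = math.log(700.0)  # lognormal median ~ 700
    pop_sigma_log: float = 0.7
    mean_household_size: float = 3.8
    hci_beta0: float = 0.18  # center intercept
    hci_beta1: float = 0.24  # slope over normalized center distance
    hci_noise_sd: float = 0.02
    dengue_r0: float = 0.025  # per-person central rate
    dengue_decay: float = 3.0  # decay over normalized center distance
    n_active_hubs: int = 2
    n_candidates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not 0 <= self.edge_dropout < 1:
            raise ValueError("edge_dropout must be in [0, 1)")
        for name in ("spacing_m", "mean_household_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_neighborhoods", "n_active_hubs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SyntheticCity:
    network: RoadNetwork
    neighborhoods: list[Neighborhood]
    facilities: list[Facility]
    config: CityConfig


def generate_network(config: CityConfig) -> RoadNetwork:
    """Jittered rows x cols grid with Euclidean edge lengths.

    A random spanning tree is protected before dropout, so the result is
    connected by construction for any seed.
    """
    rng = np.random.default_rng(config.seed)
    graph = nx.Graph()
    for r in range(config.rows):
        for c in range(config.cols):
            jx, jy = rng.uniform(-config.jitter_m, config.jitter_m, size=2)
            graph.add_node(
                f"n{r}_{c}",
                pos=(c * config.spacing_m + float(jx), r * config.spacing_m + float(jy)),
            )
    for r in range(config.rows):
        for c in range(config.cols):
            if c + 1 < config.cols:
                _add_edge(graph, f"n{r}_{c}", f"n{r}_{c + 1}")
            if r + 1 < config.rows:
                _add_edge(graph, f"n{r}_{c}", f"n{r + 1}_{c}")

    if config.edge_dropout > 0:
        # random spanning tree via random edge weights -> guards connectivity
        for u, v in graph.edges():
            graph.edges[u, v]["_w"] = rng.random()
        tree = set(
            frozenset(e) for e in nx.minimum_spanning_edges(graph, weight="_w", data=False)
        )
        removable = sorted(
            (e for e in graph.edges() if frozenset(e) not in tree),
            key=lambda e: (e[0], e[1]),
        )
        n_drop = min(len(removable), round(config.edge_dropout * graph.number_of_edges()))
        drop_idx = rng.choice(len(removable), size=n_drop, replace=False)
        for i in sorted(drop_idx.tolist()):
            graph.remove_edge(*removable[i])
        for u, v in graph.edges():
            del graph.edges[u, v]["_w"]

    return RoadNetwork(graph)


def _add_edge(graph: nx.Graph, u: str, v: str) -> None:
    length_m = math.dist(graph.nodes[u]["pos"], graph.nodes[v]["pos"])
    graph.add_edge(u, v, length_km=length_m / 1000.0)


def _center_distances(network: RoadNetwork) -> tuple[dict, tuple[float, float], float]:
    center = network.coordinate_centroid()
    dists = {
        node: math.dist(network.position(node), center)
        for node in network.graph.nodes()
    }
    return dists, center, max(dists.values())


def generate_neighborhoods(
    network: RoadNetwork, config: CityConfig
) -> list[Neighborhood]:
    """Sample neighborhood centroids near random edges and draw their
    attributes from the configured spatial models.

    HCI = clamp01(beta0 + beta1 * dist_norm + noise); cases ~
    Poisson(population * r0 * exp(-decay * dist_norm)) with dist_norm
    the straight-line distance to the network's coordinate centroid,
    normalized by its maximum over nodes.
    """
    rng = np.random.default_rng(config.seed + 1)
    edges = sorted(network.graph.edges(), key=lambda e: (str(e[0]), str(e[1])))
    lengths = np.array([network.edge_length_km(u, v) for u, v in edges])
    probs = lengths / lengths.sum()
    _, center, max_dist = _center_distances(network)

    out: list[Neighborhood] = []
    width = len(str(config.n_neighborhoods - 1))
    for i in range(config.n_neighborhoods):
        u, v = edges[int(rng.choice(len(edges), p=probs))]
        (ux, uy), (vx, vy) = network.position(u), network.position(v)
        t = float(rng.uniform(0.05, 0.95))
        px, py = ux + t * (vx - ux), uy + t * (vy - uy)
        # perpendicular offset keeps centroids off the roads but well
        # within the snap tolerance
        seg = math.hypot(vx - ux, vy - uy)
        nxv, nyv = -(vy - uy) / seg, (vx - ux) / seg
        off = float(rng.uniform(15.0, 110.0)) * (1 if rng.random() < 0.5 else -1)
        px, py = px + off * nxv, py + off * nyv

        dist_norm = math.dist((px, py), center) / max_dist
        population = int(round(float(rng.lognormal(config.pop_mu_log, config.pop_sigma_log))))
        population = max(population, 1)
        households = max(1, round(population / config.mean_household_size))
        hci = float(
            np.clip(
                config.hci_beta0
                + config.hci_beta1 * dist_norm
                + rng.normal(0.0, config.hci_noise_sd),
                0.0,
                1.0,
            )
        )
        rate = config.dengue_r0 * math.exp(-config.dengue_decay * dist_norm)
        cases = int(rng.poisson(population * rate))
        out.append(
            Neighborhood(
                id=f"b{i:0{width}d}",
                centroid=(px, py),
                population=population,
                households=households,
                hci=hci,
                dengue_cases=cases,
            )
        )
    return out


def place_facilities(network: RoadNetwork, config: CityConfig) -> list[Facility]:
    """Active hubs sampled from the innermost ~2% of nodes by center
    distance (truly central, so hub-distance bands track the radial
    attribute gradients); candidate subcenters stratified over the four
    quadrants, drawn from the outer half so they are dispersed."""
    rng = np.random.default_rng(config.seed + 2)
    dists, center, _ = _center_distances(network)
    nodes = sorted(dists, key=lambda n: (dists[n], str(n)))

    inner = nodes[: max(config.n_active_hubs, len(nodes) // 50)]
    if len(inner) < config.n_active_hubs:
        raise ValueError("not enough nodes for the requested active hubs")
    hub_nodes = [inner[i] for i in rng.choice(len(inner), size=config.n_active_hubs, replace=False)]
    facilities = [
        Facility(f"hub{i + 1}", network.position(n), "active")
        for i, n in enumerate(hub_nodes)
    ]

    if config.n_candidates:
        outer = set(nodes[len(nodes) // 2:])
        quadrants: dict[tuple[bool, bool], list[str]] = {}
        for n in nodes:
            if n in set(hub_nodes):
                continue
            x, y = network.position(n)
            quadrants.setdefault((x >= center[0], y >= center[1]), []).append(n)
        per_quad = _split_counts(config.n_candidates, len(quadrants))
        chosen: list[str] = []
        for (quad, members), want in zip(sorted(quadrants.items()), per_quad):
            pool = [n for n in members if n in outer] or members
            take = min(want, len(pool))
            idx = rng.choice(len(pool), size=take, replace=False)
            chosen.extend(pool[i] for i in sorted(idx.tolist()))
        facilities.extend(
            Facility(f"sub{i + 1}", network.position(n), "candidate")
            for i, n in enumerate(chosen)
        )
    return facilities


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_city(config: CityConfig = CityConfig()) -> SyntheticCity:
    network = generate_network(config)
    neighborhoods = generate_neighborhoods(network, config)
    facilities = place_facilities(network, config)
    return SyntheticCity(network, neighborhoods, facilities, config)


def write_city(city: SyntheticCity, out_dir) -> dict[str, str]:
    """Write network GeoJSON, neighborhoods CSV, facilities GeoJSON and a
    config sidecar; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": str(out / "network.geojson"),
        "neighborhoods": str(out / "neighborhoods.csv"),
        "facilities": str(out / "facilities.geojson"),
        "config": str(out / "city_config.json"),
    }
    write_network_geojson(city.network, paths["network"])
    write_neighborhoods_csv(city.neighborhoods, paths["neighborhoods"])
    write_facilities_geojson(city.facilities, paths["facilities"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(city.config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
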