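"""Closest-facility routing and the capacitated trip/fuel cost model.

Spray teams treat a fixed number of households per deployment and return
to their hub to refill, so treating a whole neighborhood costs
``trips x round-trip fuel cost`` where trips is the ceiling of
households over per-trip capacity.  Costs are kept at full float
precision internally; rounding to cents happens only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census_attributes import Neighborhood
from .road_network import RoadNetwork, Route, shortest_path

__all__ = [
    "CostModel",
    "NeighborhoodCost",
    "closest_facility",
    "trips_required",
    "round_trip_fuel_cost",
    "neighborhood_access_cost",
    "cost_bin_summary",
    "quantile_cost_edges",
]


@dataclass(frozen=True)
class CostModel:
    """Fuel price, fuel economy, and per-trip spray capacity."""

    fuel_price_per_l: float = 0.61  # USD/L, Ecuador 2016 average
    fuel_economy_km_per_l: float = 5.53  # 2010 pickup truck, city driving
    households_per_trip: int = 25  # backpack-sprayer capacity per deployment
    round_trip_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.fuel_price_per_l <= 0:
            raise ValueError("fuel_price_per_l must be positive")
        if self.fuel_economy_km_per_l <= 0:
            raise ValueError("fuel_economy_km_per_l must be positive")
        if int(self.households_per_trip) != self.households_per_trip or self.households_per_trip < 1:
            raise ValueError("households_per_trip must be an integer >= 1")
        if self.round_trip_factor <= 0:
            raise ValueError("round_trip_factor must be positive")


@dataclass(frozen=True)
class NeighborhoodCost:
    neighborhood_id: Hashable
    facility_id: Hashable
    one_way_km: float
    trips: int
    per_trip_cost_usd: float
    total_cost_usd: float


def closest_facility(
    network: RoadNetwork,
    facility_nodes: Mapping[Hashable, Hashable],
    demand_node: Hashable,
) -> tuple[Hashable, Route] | None:
    """Facility (id) with the minimal-length route to the demand node.

    ``facility_nodes`` maps facility id -> snapped graph node.  Ties are
    broken by the smallest facility id (string order).  Returns ``None``
    when no facility can reach the demand node.
    """
    if not facility_nodes:
        raise ValueError("at least one facility required")
    best: tuple[float, str, Hashable, Route] | None = None
    for fid in sorted(facility_nodes, key=str):
        route = shortest_path(network, facility_nodes[fid], demand_node)
        if route is None:
            continue
        key = (route.length_km, str(fid))
        if best is None or key < (best[0], best[1]):
            best = (route.length_km, str(fid), fid, route)
    if best is None:
        return None
    return best[2], best[3]


def trips_required(households: int, model: CostModel = CostModel()) -> int:
    """Deployments needed to treat every household once:
    ``ceil(households / capacity)``; zero households need zero trips."""
    if households < 0:
        raise ValueError("negative household count")
    return math.ceil(households / model.households_per_trip)


def round_trip_fuel_cost(one_way_km: float, model: CostModel = CostModel()) -> float:
    """Fuel cost (USD) of one hub -> neighborhood -> hub trip."""
    if one_way_km < 0:
        raise ValueError("negative route length")
    litres = model.round_trip_factor * one_way_km / model.fuel_economy_km_per_l
    return litres * model.fuel_price_per_l


def neighborhood_access_cost(
    route: Route,
    households: int,
    model: CostModel = CostModel(),
    neighborhood_id: Hashable | None = None,
    facility_id: Hashable | None = None,
) -> NeighborhoodCost:
    """Total fuel cost to treat every household in a neighborhood once."""
    trips = trips_required(households, model)
    per_trip = round_trip_fuel_cost(route.length_km, model)
    return NeighborhoodCost(
        neighborhood_id=neighborhood_id
        if neighborhood_id is not None
        else route.destination_node_id,
        facility_id=facility_id if facility_id is not None else route.origin_node_id,
        one_way_km=route.length_km,
        trips=trips,
        per_trip_cost_usd=per_trip,
        total_cost_usd=trips * per_trip,
    )


def quantile_cost_edges(costs: Sequence[float], n_classes: int = 5) -> list[float]:
    """Internal class breaks at evenly spaced quantiles of the cost
    distribution (the default classing when no explicit edges are given)."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    qs = np.linspace(0, 1, n_classes + 1)[1:-1]
    edges = list(np.quantile(np.asarray(costs, dtype=float), qs))
    # collapse duplicate breaks (degenerate distributions)
    unique = []
    for e in edges:
        if not unique or e > unique[-1]:
            unique.append(float(e))
    return unique


def cost_bin_summary(
    costs: Sequence[NeighborhoodCost],
    neighborhoods: Sequence[Neighborhood],
    edges: Sequence[float] | None = None,
    mean_hci_weighted: bool = False,
) -> pd.DataFrame:
    """Summarize demand by total-access-cost class (count, population,
    mean HCI, pooled incidence).

    ``edges`` are strictly increasing internal break values; class ``i``
    is upper-closed, i.e. ``(edges[i-1], edges[i]]`` with open-ended
    first and last classes.  Defaults to quintile breaks of the observed
    cost distribution.
    """
    if not costs:
        raise ValueError("no costs to summarize")
    if edges is None:
        edges = quantile_cost_edges([c.total_cost_usd for c in costs])
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("cost class edges must be strictly increasing")

    by_id = {n.id: n for n in neighborhoods}
    n_classes = len(edges) + 1
    members: dict[int, list[tuple[NeighborhoodCost, Neighborhood]]] = {
        i: [] for i in range(n_classes)
    }
    for cost in costs:
        idx = _class_index(cost.total_cost_usd, edges)
        members[idx].append((cost, by_id[cost.neighborhood_id]))

    rows = []
    for i in range(n_classes):
        group = members[i]
        population = sum(n.population for _, n in group)
        cases = sum(n.dengue_cases for _, n in group)
        if group:
            if mean_hci_weighted and population > 0:
                mean_hci = sum(n.hci * n.population for _, n in group) / population
            else:
                mean_hci = float(np.mean([n.hci for _, n in group]))
        else:
            mean_hci = math.nan
        rows.append(
            {
                "cost_class": _class_label(i, edges),
                "n_neighborhoods": len(group),
                "population": population,
                "mean_hci": mean_hci,
                "incidence_per_10k": cases / population * 10_000.0
                if population > 0
                else math.nan,
            }
        )
    return pd.DataFrame(rows)


def _class_index(value: float, edges: Sequence[float]) -> int:
    for i, edge in enumerate(edges):
        if value <= edge:
            return i
    return len(edges)


def _class_label(i: int, edges: Sequence[float]) -> str:
    if i == 0:
        return f"≤ {edges[0]:.2f}"
    if i == len(edges):
        return f"> {edges[-1]:.2f}"
    return f"{edges[i - 1]:.2f}–{edges[i]:.2f}"
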