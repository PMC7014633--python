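"""End-to-end orchestration: load or generate a city, snap everything,
bin service areas, cost the optimized routes, run location-allocation
scenarios, and write the report bundle.

Outputs (all plain text, deterministic for a fixed config + seed):

- ``neighborhoods_out.csv`` — per reachable neighborhood: nearest-hub
  distance, service bin, closest facility, trips, per-trip and total
  cost (full precision and cent-rounded).
- ``unreachable.csv`` — neighborhoods beyond the snap tolerance or cut
  off from every facility.
- ``bins_summary.csv`` — service-area bin summary.
- ``cost_classes.csv`` — cost-class summary of the baseline scenario.
- ``routes.geojson`` — closest-facility route per neighborhood.
- ``allocation_<mode>.json`` / ``comparison_<mode>.json`` — per
  weighting scenario.
- ``run_config.json`` — echo of the effective configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import location_allocation as la
from . import route_costing as rc
from . import service_areas as sa
from .census_attributes import Neighborhood, read_neighborhoods
from .facilities import Facility, read_facilities
from .road_network import (
    RoadNetwork,
    SnapConfig,
    distance_matrix,
    read_network_csv,
    read_network_geojson,
    snap_points,
    write_routes_geojson,
)
from .synthetic_city import CityConfig, generate_city

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_inputs"]

logger = logging.getLogger("vectorops")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass(frozen=True)
class RunConfig:
    # file inputs (either these or `synth`)
    network_path: str | None = None
    nodes_csv: str | None = None
    edges_csv: str | None = None
    neighborhoods_path: str | None = None
    facilities_path: str | None = None
    grade_maxima: tuple[float, ...] | None = None
    # or generate a synthetic city
    synth: CityConfig | None = None
    # analysis knobs
    snap: SnapConfig = SnapConfig()
    scheme: sa.ServiceBinScheme = sa.ServiceBinScheme()
    cost_model: rc.CostModel = rc.CostModel()
    allocation: la.AllocationConfig = la.AllocationConfig()
    modes: tuple[str, ...] = la.WEIGHTING_MODES
    cost_class_edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        has_files = self.neighborhoods_path is not None and (
            self.network_path is not None
            or (self.nodes_csv is not None and self.edges_csv is not None)
        )
        if self.synth is None and not has_files:
            raise PipelineError(
                "config: provide either synth parameters or input paths "
                "(network + neighborhoods + facilities)"
            )
        unknown = set(self.modes) - set(la.WEIGHTING_MODES)
        if unknown:
            raise PipelineError(f"config: unknown weighting modes {sorted(unknown)}")

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RunConfig":
        def sub(key, klass):
            return klass(**doc[key]) if key in doc and doc[key] is not None else None

        kwargs: dict[str, Any] = {
            k: doc[k]
            for k in (
                "network_path",
                "nodes_csv",
                "edges_csv",
                "neighborhoods_path",
                "facilities_path",
            )
            if k in doc
        }
        if "grade_maxima" in doc and doc["grade_maxima"] is not None:
            kwargs["grade_maxima"] = tuple(doc["grade_maxima"])
        synth = sub("synth", CityConfig)
        if synth is not None:
            kwargs["synth"] = synth
        if (snap := sub("snap", SnapConfig)) is not None:
            kwargs["snap"] = snap
        if "bins" in doc and doc["bins"] is not None:
            bins = dict(doc["bins"])
            if "cutoffs_km" in bins:
                bins["cutoffs_km"] = tuple(bins["cutoffs_km"])
            if "labels" in bins and bins["labels"] is not None:
                bins["labels"] = tuple(bins["labels"])
            kwargs["scheme"] = sa.ServiceBinScheme(**bins)
        if (model := sub("cost_model", rc.CostModel)) is not None:
            kwargs["cost_model"] = model
        if (alloc := sub("allocation", la.AllocationConfig)) is not None:
            kwargs["allocation"] = alloc
        if "modes" in doc and doc["modes"] is not None:
            kwargs["modes"] = tuple(doc["modes"])
        if "cost_class_edges" in doc and doc["cost_class_edges"] is not None:
            kwargs["cost_class_edges"] = tuple(doc["cost_class_edges"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------


def _load_city(config: RunConfig):
    if config.synth is not None:
        city = generate_city(config.synth)
        return city.network, city.neighborhoods, city.facilities
    try:
        if config.network_path is not None:
            network = read_network_geojson(config.network_path)
        else:
            network = read_network_csv(config.nodes_csv, config.edges_csv)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"load-network: {exc}") from exc
    try:
        neighborhoods = read_neighborhoods(
            config.neighborhoods_path, grade_maxima=config.grade_maxima
        )
    except (OSError, ValueError) as exc:
        raise PipelineError(f"load-neighborhoods: {exc}") from exc
    try:
        facilities = read_facilities(config.facilities_path)
    except (OSError, TypeError, ValueError, KeyError) as exc:
        raise PipelineError(f"load-facilities: {exc}") from exc
    return network, neighborhoods, facilities


def _snap_all(network, neighborhoods, facilities, snap_config):
    points = {("fac", f.id): f.location for f in facilities}
    points.update({("nbhd", n.id): n.centroid for n in neighborhoods})
    results = snap_points(network, points, snap_config)
    fac_nodes = {
        f.id: results[("fac", f.id)].attached_node_id
        for f in facilities
        if results[("fac", f.id)].reachable
    }
    nbhd_nodes = {
        n.id: results[("nbhd", n.id)].attached_node_id
        for n in neighborhoods
        if results[("nbhd", n.id)].reachable
    }
    return fac_nodes, nbhd_nodes, results


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> dict[str, str]:
    """Run every stage and write the report bundle into ``out_dir``.

    ``seed`` overrides the synthetic-city and heuristic-solver seeds.
    Returns a name -> path map of the written artifacts.
    """
    if seed is not None:
        if config.synth is not None:
            config = dataclasses.replace(
                config, synth=dataclasses.replace(config.synth, seed=seed)
            )
        config = dataclasses.replace(
            config, allocation=dataclasses.replace(config.allocation, seed=seed)
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    network, neighborhoods, facilities = _load_city(config)
    logger.info(
        "loaded network: %d nodes, %d edges, %d component(s)",
        network.n_nodes, network.n_edges, network.connected_component_count(),
    )
    active = [f for f in facilities if f.role == "active"]
    if not active:
        raise PipelineError("facilities: no active facility present")

    # -- snap ------------------------------------------------------------
    fac_nodes, nbhd_nodes, snap_results = _snap_all(
        network, neighborhoods, facilities, config.snap
    )
    missing_fac = [f.id for f in facilities if f.id not in fac_nodes]
    if any(f.role == "active" for f in facilities if f.id in missing_fac):
        raise PipelineError(f"snap: active facility out of tolerance: {missing_fac}")
    active_nodes = [fac_nodes[f.id] for f in active]

    # -- service-area distances & reachability ---------------------------
    distances = sa.min_facility_distances(
        network, active_nodes, list(nbhd_nodes.values())
    )
    dist_by_id = {nid: distances[node] for nid, node in nbhd_nodes.items()}
    reachable = [
        n for n in neighborhoods
        if n.id in dist_by_id and not math.isinf(dist_by_id[n.id])
    ]
    unreachable_rows = []
    for n in neighborhoods:
        if n.id not in nbhd_nodes:
            unreachable_rows.append(
                {"id": n.id, "reason": "outside snap tolerance",
                 "offset_m": snap_results[("nbhd", n.id)].offset_m}
            )
        elif math.isinf(dist_by_id[n.id]):
            unreachable_rows.append(
                {"id": n.id, "reason": "disconnected from active facilities",
                 "offset_m": snap_results[("nbhd", n.id)].offset_m}
            )
    for row in unreachable_rows:
        logger.warning("excluded neighborhood %s: %s", row["id"], row["reason"])
    paths["unreachable"] = str(out / "unreachable.csv")
    pd.DataFrame(unreachable_rows, columns=["id", "reason", "offset_m"]).to_csv(
        paths["unreachable"], index=False
    )

    # -- bins (Table 1 analog) -------------------------------------------
    bins = sa.summarize_bins(reachable, dist_by_id, config.scheme)
    paths["bins_summary"] = str(out / "bins_summary.csv")
    bins.to_csv(paths["bins_summary"], index=False)

    # -- closest-facility routes and costs -------------------------------
    active_node_map = {f.id: fac_nodes[f.id] for f in active}
    routes, costs = [], []
    for n in reachable:
        hit = rc.closest_facility(network, active_node_map, nbhd_nodes[n.id])
        fid, route = hit
        routes.append(route)
        costs.append(
            rc.neighborhood_access_cost(
                route, n.households, config.cost_model,
                neighborhood_id=n.id, facility_id=fid,
            )
        )
    paths["routes"] = str(out / "routes.geojson")
    write_routes_geojson(routes, network, paths["routes"])

    out_frame = pd.DataFrame(
        {
            "id": [c.neighborhood_id for c in costs],
            "min_facility_km": [dist_by_id[c.neighborhood_id] for c in costs],
            "bin_label": [
                sa.assign_bin(dist_by_id[c.neighborhood_id], config.scheme)
                for c in costs
            ],
            "facility_id": [c.facility_id for c in costs],
            "one_way_km": [c.one_way_km for c in costs],
            "trips": [c.trips for c in costs],
            "per_trip_cost_usd": [c.per_trip_cost_usd for c in costs],
            "per_trip_cost_usd_rounded": [round(c.per_trip_cost_usd, 2) for c in costs],
            "total_cost_usd": [c.total_cost_usd for c in costs],
            "total_cost_usd_rounded": [round(c.total_cost_usd, 2) for c in costs],
        }
    )
    paths["neighborhoods_out"] = str(out / "neighborhoods_out.csv")
    out_frame.to_csv(paths["neighborhoods_out"], index=False)

    # -- cost classes (Table 2 analog) -----------------------------------
    if config.cost_class_edges is not None:
        class_edges = list(config.cost_class_edges)
    else:
        class_edges = rc.quantile_cost_edges([c.total_cost_usd for c in costs])
    classes = rc.cost_bin_summary(costs, reachable, class_edges)
    paths["cost_classes"] = str(out / "cost_classes.csv")
    classes.to_csv(paths["cost_classes"], index=False)

    # -- location-allocation scenarios (Fig. 6 / Table 3 analog) ---------
    candidate_map = {f.id: fac_nodes[f.id] for f in facilities if f.id in fac_nodes}
    dm = distance_matrix(
        network, list(candidate_map.values()), [nbhd_nodes[n.id] for n in reachable]
    )
    dm.index = list(candidate_map.keys())
    dm.columns = [n.id for n in reachable]

    for mode in config.modes:
        weights = la.scenario_weights(reachable, mode)
        result = la.solve(dm, list(candidate_map.keys()), config.allocation, weights)
        logger.info("allocation[%s]: solver=%s selected=%s", mode, result.solver,
                    result.selected)
        paths[f"allocation_{mode}"] = str(out / f"allocation_{mode}.json")
        with open(paths[f"allocation_{mode}"], "w") as fh:
            json.dump(
                {
                    "mode": mode,
                    "selected": [str(s) for s in result.selected],
                    "objective": result.objective,
                    "solver": result.solver,
                    "assignments": {
                        str(k): str(v) for k, v in sorted(result.assignments.items())
                    },
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")

        alt_costs = _scenario_costs(dm, result.selected, reachable, config.cost_model)
        metrics = la.compare_scenarios(costs, alt_costs, reachable, class_edges)
        paths[f"comparison_{mode}"] = str(out / f"comparison_{mode}.json")
        with open(paths[f"comparison_{mode}"], "w") as fh:
            json.dump(
                {
                    "mode": mode,
                    "mean_cost_reduction_pct": metrics.mean_cost_reduction_pct,
                    "cheapest_class_population_change_pct":
                        metrics.cheapest_class_population_change_pct,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")

    # -- config echo -----------------------------------------------------
    paths["run_config"] = str(out / "run_config.json")
    with open(paths["run_config"], "w") as fh:
        json.dump(_config_dict(config), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return paths


def _scenario_costs(
    dm: pd.DataFrame,
    selected: Sequence,
    neighborhoods: Sequence[Neighborhood],
    model: rc.CostModel,
) -> list[rc.NeighborhoodCost]:
    """Closest-facility costs when service deploys from ``selected``
    (facility assignment and one-way distance read off the matrix)."""
    ordered = sorted(selected, key=str)
    sub = dm.loc[ordered]
    out = []
    for n in neighborhoods:
        col = sub[n.id]
        fid = col.idxmin()  # first minimum = smallest facility id
        trips = rc.trips_required(n.households, model)
        per_trip = rc.round_trip_fuel_cost(float(col[fid]), model)
        out.append(
            rc.NeighborhoodCost(
                neighborhood_id=n.id,
                facility_id=fid,
                one_way_km=float(col[fid]),
                trips=trips,
                per_trip_cost_usd=per_trip,
                total_cost_usd=trips * per_trip,
            )
        )
    return out


def _config_dict(config: RunConfig) -> dict:
    doc = dataclasses.asdict(config)
    return doc


def validate_inputs(config: RunConfig) -> list[dict]:
    """Report structural problems without running any analysis.

    Returns a list of ``{"stage", "id", "problem"}`` records; empty means
    the inputs are clean.
    """
    problems: list[dict] = []
    try:
        network, neighborhoods, facilities = _load_city(config)
    except PipelineError as exc:
        return [{"stage": "load", "id": None, "problem": str(exc)}]

    n_components = network.connected_component_count()
    if n_components != 1:
        problems.append(
            {
                "stage": "network",
                "id": None,
                "problem": f"network has {n_components} connected components",
            }
        )

    work = network.copy()
    fac_nodes, nbhd_nodes, results = _snap_all(
        work, neighborhoods, facilities, config.snap
    )
    for f in facilities:
        res = results[("fac", f.id)]
        if not res.reachable:
            problems.append(
                {
                    "stage": "snap",
                    "id": f.id,
                    "problem": f"facility {res.offset_m:.0f} m from nearest road "
                    f"(tolerance {config.snap.tolerance_m:.0f} m)",
                }
            )
    for n in neighborhoods:
        res = results[("nbhd", n.id)]
        if not res.reachable:
            problems.append(
                {
                    "stage": "snap",
                    "id": n.id,
                    "problem": f"neighborhood {res.offset_m:.0f} m from nearest road "
                    f"(tolerance {config.snap.tolerance_m:.0f} m)",
                }
            )
    active_nodes = [
        fac_nodes[f.id] for f in facilities if f.role == "active" and f.id in fac_nodes
    ]
    if active_nodes:
        dists = sa.min_facility_distances(work, active_nodes, list(nbhd_nodes.values()))
        node_to_id = {v: k for k, v in nbhd_nodes.items()}
        for node, dist in dists.items():
            if math.isinf(dist):
                problems.append(
                    {
                        "stage": "connectivity",
                        "id": node_to_id[node],
                        "problem": "neighborhood disconnected from active facilities",
                    }
                )
        for f in facilities:
            if f.id in fac_nodes and f.role != "active":
                reach = sa.min_facility_distances(work, active_nodes, [fac_nodes[f.id]])
                if math.isinf(reach[fac_nodes[f.id]]):
                    problems.append(
                        {
                            "stage": "connectivity",
                            "id": f.id,
                            "problem": "facility on a component isolated from active hubs",
                        }
                    )
    else:
        problems.append(
            {"stage": "facilities", "id": None, "problem": "no reachable active facility"}
        )
    return problems
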