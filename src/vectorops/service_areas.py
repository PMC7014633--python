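"""Driving-distance service-area bins and per-bin demand summaries.

Every reachable neighborhood is characterized by its network distance to
the *nearest* active facility and assigned to one distance bin; per-bin
summaries report neighborhood count, total population, mean HCI, and
pooled dengue incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .census_attributes import Neighborhood
from .road_network import RoadNetwork

__all__ = [
    "ServiceBinScheme",
    "min_facility_distance",
    "min_facility_distances",
    "assign_bin",
    "summarize_bins",
]

DEFAULT_CUTOFFS_KM = (0.5, 1.0, 3.0, 5.0)


@dataclass(frozen=True)
class ServiceBinScheme:
    """Ordered distance cutoffs (km) defining upper-closed bins.

    Cutoffs ``(0.5, 1, 3, 5)`` produce the bins [0, 0.5], (0.5, 1],
    (1, 3], (3, 5], (5, inf) labelled "0.0-0.5", "0.6-1.0", "1.1-3.0",
    "3.1-5.0", "> 5" (report-style labels with a 0.1 km printed gap).
    """

    cutoffs_km: tuple[float, ...] = DEFAULT_CUTOFFS_KM
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutoffs_km)
        if not cuts or any(c <= 0 for c in cuts):
            raise ValueError("cutoffs must be positive")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        object.__setattr__(self, "cutoffs_km", cuts)
        if self.labels is None:
            object.__setattr__(self, "labels", self._default_labels())
        elif len(self.labels) != len(cuts) + 1:
            raise ValueError("need one label per bin (len(cutoffs) + 1)")

    def _default_labels(self) -> tuple[str, ...]:
        labels = [f"0.0–{self.cutoffs_km[0]:.1f}"]
        for lower, upper in zip(self.cutoffs_km, self.cutoffs_km[1:]):
            labels.append(f"{lower + 0.1:.1f}–{upper:.1f}")
        labels.append(f"> {self.cutoffs_km[-1]:g}")
        return tuple(labels)

    @property
    def n_bins(self) -> int:
        return len(self.cutoffs_km) + 1

    def bin_index(self, distance_km: float) -> int:
        if distance_km < 0:
            raise ValueError(f"negative distance {distance_km}")
        for i, cutoff in enumerate(self.cutoffs_km):
            if distance_km <= cutoff:
                return i
        return len(self.cutoffs_km)


def assign_bin(distance_km: float, scheme: ServiceBinScheme) -> str:
    """Label of the distance bin containing ``distance_km`` (intervals
    closed on their upper edge)."""
    return scheme.labels[scheme.bin_index(distance_km)]


def min_facility_distances(
    network: RoadNetwork,
    facility_nodes: Sequence[Hashable],
    demand_nodes: Sequence[Hashable],
) -> dict[Hashable, float]:
    """Network distance from each demand node to its nearest facility.

    One multi-source Dijkstra pass; nodes unreachable from every
    facility map to ``inf``.
    """
    if not facility_nodes:
        raise ValueError("at least one facility node required")
    lengths = nx.multi_source_dijkstra_path_length(
        network.graph, set(facility_nodes), weight="length_km"
    )
    return {d: lengths.get(d, math.inf) for d in demand_nodes}


def min_facility_distance(
    network: RoadNetwork,
    facility_nodes: Sequence[Hashable],
    demand_node: Hashable,
) -> float:
    return min_facility_distances(network, facility_nodes, [demand_node])[demand_node]


def summarize_bins(
    neighborhoods: Sequence[Neighborhood],
    distances_km: Mapping[Hashable, float],
    scheme: ServiceBinScheme = ServiceBinScheme(),
    mean_hci_weighted: bool = False,
) -> pd.DataFrame:
    """Per-bin summary table.

    Columns: ``bin_label, n_neighborhoods, population, mean_hci,
    incidence_per_10k``.  Mean HCI is the unweighted mean over
    neighborhoods (population-weighted when ``mean_hci_weighted``);
    incidence is pooled cases over pooled population.  Empty or
    zero-population bins report NaN for the undefined statistics.
    Neighborhoods with infinite distance (unreachable) are excluded.
    """
    rows = []
    by_bin: dict[int, list[Neighborhood]] = {i: [] for i in range(scheme.n_bins)}
    for nbhd in neighborhoods:
        dist = distances_km[nbhd.id]
        if math.isinf(dist):
            continue
        by_bin[scheme.bin_index(dist)].append(nbhd)

    for i in range(scheme.n_bins):
        members = by_bin[i]
        population = sum(n.population for n in members)
        cases = sum(n.dengue_cases for n in members)
        if members:
            if mean_hci_weighted and population > 0:
                mean_hci = sum(n.hci * n.population for n in members) / population
            else:
                mean_hci = float(np.mean([n.hci for n in members]))
        else:
            mean_hci = math.nan
        incidence = cases / population * 10_000.0 if population > 0 else math.nan
        rows.append(
            {
                "bin_label": scheme.labels[i],
                "n_neighborhoods": len(members),
                "population": population,
                "mean_hci": mean_hci,
                "incidence_per_10k": incidence,
            }
        )
    return pd.DataFrame(rows)
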