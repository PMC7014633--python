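"""Demand-side data model: neighborhoods, housing condition, incidence.

A neighborhood is the demand unit of the whole analysis: a census-block
centroid carrying population, household count, a housing condition
index (HCI, 0 = excellent .. 1 = very poor), and a dengue case count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Sequence

import pandas as pd

__all__ = [
    "CensusValidationError",
    "Neighborhood",
    "compute_hci",
    "incidence_per_10k",
    "read_neighborhoods",
    "write_neighborhoods_csv",
]

DEFAULT_MEAN_HOUSEHOLD_SIZE = 3.8


class CensusValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Neighborhood:
    id: Hashable
    centroid: tuple[float, float]  # planar metres
    population: int
    households: int
    hci: float
    dengue_cases: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise CensusValidationError(f"{self.id!r}: negative population")
        if self.households < 0:
            raise CensusValidationError(f"{self.id!r}: negative households")
        if self.dengue_cases < 0:
            raise CensusValidationError(f"{self.id!r}: negative dengue_cases")
        if not 0.0 <= self.hci <= 1.0:
            raise CensusValidationError(f"{self.id!r}: hci {self.hci} outside [0, 1]")


def compute_hci(
    roof_grade: float,
    wall_grade: float,
    floor_grade: float,
    grade_maxima: Sequence[float],
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Composite housing condition index in [0, 1].

    Each condition grade (0 = best, maximum = worst) is normalized by
    its stated maximum and the three are combined by a weighted mean
    (equal weights by default).
    """
    grades = (roof_grade, wall_grade, floor_grade)
    if len(grade_maxima) != 3:
        raise CensusValidationError("grade_maxima must have three entries")
    if len(weights) != 3 or sum(weights) <= 0:
        raise CensusValidationError("weights must be three values with positive sum")
    normalized = []
    for name, grade, maximum in zip(("roof", "wall", "floor"), grades, grade_maxima):
        if maximum <= 0:
            raise CensusValidationError(f"{name} grade maximum must be positive")
        if not 0 <= grade <= maximum:
            raise CensusValidationError(
                f"{name} grade {grade} outside [0, {maximum}]"
            )
        normalized.append(grade / maximum)
    return sum(w * g for w, g in zip(weights, normalized)) / sum(weights)


def incidence_per_10k(cases: float, population: float) -> float:
    """Cases per 10,000 population."""
    if population <= 0:
        raise CensusValidationError("incidence undefined for population <= 0")
    if cases < 0:
        raise CensusValidationError("negative case count")
    return cases / population * 10_000.0


_REQUIRED = ("id", "x", "y", "population", "dengue_cases")


def read_neighborhoods(
    path,
    grade_maxima: Sequence[float] | None = None,
    mean_household_size: float = DEFAULT_MEAN_HOUSEHOLD_SIZE,
) -> list[Neighborhood]:
    """Read neighborhoods from CSV or a GeoJSON FeatureCollection of points.

    Expected CSV columns: ``id,x,y,population,households,roof,wall,floor
    [,hci],dengue_cases``; the same keys appear as GeoJSON properties
    (coordinates supply x, y).  When ``hci`` is absent it is computed
    from the three grades, which then requires ``grade_maxima``.  A
    missing ``households`` column is imputed as
    ``round(population / mean_household_size)``.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        frame = _geojson_points_frame(path)
    else:
        frame = pd.read_csv(path)

    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise CensusValidationError(f"missing required columns: {missing}")

    imputed = "households" not in frame.columns
    out: list[Neighborhood] = []
    for _, row in frame.iterrows():
        if "hci" in frame.columns and not _isna(row.get("hci")):
            hci = float(row["hci"])
        else:
            if grade_maxima is None:
                raise CensusValidationError(
                    "no hci column: grade_maxima required to compute HCI from grades"
                )
            hci = compute_hci(
                float(row["roof"]), float(row["wall"]), float(row["floor"]),
                grade_maxima,
            )
        population = _count(row["population"], "population")
        if imputed or _isna(row.get("households")):
            households = round(population / mean_household_size)
        else:
            households = _count(row["households"], "households")
        out.append(
            Neighborhood(
                id=str(row["id"]),
                centroid=(float(row["x"]), float(row["y"])),
                population=population,
                households=households,
                hci=hci,
                dengue_cases=_count(row["dengue_cases"], "dengue_cases"),
            )
        )
    return out


def write_neighborhoods_csv(neighborhoods: Sequence[Neighborhood], path) -> None:
    frame = pd.DataFrame(
        {
            "id": [n.id for n in neighborhoods],
            "x": [n.centroid[0] for n in neighborhoods],
            "y": [n.centroid[1] for n in neighborhoods],
            "population": [n.population for n in neighborhoods],
            "households": [n.households for n in neighborhoods],
            "hci": [n.hci for n in neighborhoods],
            "dengue_cases": [n.dengue_cases for n in neighborhoods],
        }
    )
    frame.to_csv(path, index=False)


def _count(value, name: str) -> int:
    number = float(value)
    if number < 0:
        raise CensusValidationError(f"negative {name}: {value!r}")
    return int(round(number))


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _geojson_points_frame(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    rows = []
    for feature in doc.get("features", []):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        props = dict(feature.get("properties") or {})
        props["x"], props["y"] = geom["coordinates"][:2]
        rows.append(props)
    return pd.DataFrame(rows)
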