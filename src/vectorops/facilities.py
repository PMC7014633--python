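"""Service deployment points: active spray hubs and candidate subcenters."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Sequence

import pandas as pd

__all__ = ["Facility", "read_facilities", "write_facilities_geojson"]

ROLES = ("active", "candidate")


@dataclass(frozen=True)
class Facility:
    id: Hashable
    location: tuple[float, float]  # planar metres
    role: str  # "active" (current hub) or "candidate" (subcenter)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"facility role must be one of {ROLES}, got {self.role!r}")


def read_facilities(path) -> list[Facility]:
    """Read facilities from CSV (``id,x,y,role``) or GeoJSON points."""
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        with open(path) as fh:
            doc = json.load(fh)
        out = []
        for feature in doc.get("features", []):
            geom = feature.get("geometry") or {}
            if geom.get("type") != "Point":
                continue
            props = feature.get("properties") or {}
            x, y = geom["coordinates"][:2]
            out.append(Facility(str(props["id"]), (float(x), float(y)), props["role"]))
        return out
    frame = pd.read_csv(path)
    return [
        Facility(str(row["id"]), (float(row["x"]), float(row["y"])), str(row["role"]))
        for _, row in frame.iterrows()
    ]


def write_facilities_geojson(facilities: Sequence[Facility], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(f.location)},
            "properties": {"id": str(f.id), "role": f.role},
        }
        for f in facilities
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")
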