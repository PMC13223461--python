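"""Geospatial prevalence aggregation.

Screening records carry an optional geotag; aggregating predicted labels on
a fixed latitude/longitude grid highlights geographic clusters with high
anemia prevalence for targeted follow-up screening.  Cells are equal-degree
(not equal-area) squares anchored at (-90, -180) with half-open
``[min, min + size)`` binning; the north pole and the antimeridian are
clamped into the last cell so every valid record maps to exactly one cell.
Output is CSV or a GeoJSON FeatureCollection of cell polygons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ValidationError

__all__ = [
    "ScreeningRecord",
    "PrevalenceCell",
    "aggregate_prevalence",
    "prevalence_geojson",
]


@dataclass(frozen=True)
class ScreeningRecord:
    """One geotagged screening outcome."""

    record_id: str
    predicted_label: str
    probability: float
    latitude: float
    longitude: float
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not (abs(self.latitude) <= 90 and abs(self.longitude) <= 180):
            raise ValidationError(
                f"invalid coordinates ({self.latitude}, {self.longitude})"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability {self.probability} outside [0, 1]")


@dataclass
class PrevalenceCell:
    """Aggregated counts for one grid cell."""

    lat_min: float
    lon_min: float
    cell_size: float
    n_total: int = 0
    n_anemic: int = 0
    flagged: bool = False

    @property
    def anemic_fraction(self) -> float:
        return self.n_anemic / self.n_total if self.n_total > 0 else float("nan")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.lon_min,
            self.lat_min,
            self.lon_min + self.cell_size,
            self.lat_min + self.cell_size,
        )


def aggregate_prevalence(
    records: Iterable[ScreeningRecord],
    cell_size: float = 0.5,
    min_n: int = 5,
    threshold: float = 0.5,
    *,
    include_moderate: bool = False,
) -> list[PrevalenceCell]:
    """Bin records onto the grid and flag high-prevalence cells.

    A cell is flagged iff it holds at least ``min_n`` records and its anemic
    fraction is at least ``threshold``.  By default only the ``anemic`` class
    counts as anemic (clinical conservatism); set ``include_moderate`` to
    count moderate cases too.
    """
    if cell_size <= 0:
        raise ValidationError("cell_size must be positive")
    anemic_classes = {"anemic", "moderate"} if include_moderate else {"anemic"}
    n_lat = math.ceil(180.0 / cell_size)
    n_lon = math.ceil(360.0 / cell_size)
    cells: dict[tuple[int, int], PrevalenceCell] = {}
    for rec in records:
        iy = min(int((rec.latitude + 90.0) // cell_size), n_lat - 1)
        ix = min(int((rec.longitude + 180.0) // cell_size), n_lon - 1)
        cell = cells.get((iy, ix))
        if cell is None:
            cell = cells[(iy, ix)] = PrevalenceCell(
                lat_min=-90.0 + iy * cell_size,
                lon_min=-180.0 + ix * cell_size,
                cell_size=cell_size,
            )
        cell.n_total += 1
        if rec.predicted_label in anemic_classes:
            cell.n_anemic += 1
    out = [cells[key] for key in sorted(cells)]
    for cell in out:
        cell.flagged = cell.n_total >= min_n and cell.anemic_fraction >= threshold
    return out


def prevalence_geojson(cells: Iterable[PrevalenceCell]) -> dict:
    """GeoJSON FeatureCollection of cell polygons with prevalence properties."""
    features = []
    for c in cells:
        w, s, e, n = c.bounds
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[w, s], [e, s], [e, n], [w, n], [w, s]]],
                },
                "properties": {
                    "n_total": c.n_total,
                    "n_anemic": c.n_anemic,
                    "anemic_fraction": (
                        None if c.n_total == 0 else round(c.anemic_fraction, 6)
                    ),
                    "flagged": c.flagged,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(cells: Iterable[PrevalenceCell], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(prevalence_geojson(cells), fh, indent=2)
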