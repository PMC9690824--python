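"""Core domain types shared by every pipeline stage.

All coordinates are projected planar meters in a dimensionless local CRS;
every distance rule in the method (kernel bandwidth, buffer radii, the
catchment threshold) is metric, so geographic degrees are rejected at the
I/O boundary instead of being silently reinterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

from .errors import DataError
from .grids import GridSpec

PARK = "park"
BUFFER = "buffer"
GREEN_CATEGORIES = (PARK, BUFFER)


@dataclass(frozen=True)
class StudyArea:
    """The analysis extent: a simple polygon in planar meters."""

    boundary: Polygon

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise DataError("study-area boundary must be a valid non-empty polygon")
        if self.boundary.area <= 0:
            raise DataError("study-area boundary must have positive area")

    @property
    def area_m2(self) -> float:
        return self.boundary.area

    @property
    def area_km2(self) -> float:
        return self.boundary.area / 1e6


@dataclass(frozen=True)
class GreenSpacePolygon:
    """A green-space patch: the supply side of every service rule.

    ``category`` distinguishes park green space (recreation-eligible) from
    protective/buffer green space (cooling and disaster only).
    """

    id: str
    geometry: Polygon
    category: str

    def __post_init__(self) -> None:
        if self.category not in GREEN_CATEGORIES:
            raise DataError(
                f"green-space category must be one of {GREEN_CATEGORIES}, got {self.category!r}"
            )
        if not self.geometry.is_valid or self.geometry.is_empty:
            raise DataError(f"green space {self.id!r} has invalid or empty geometry")

    @property
    def area_m2(self) -> float:
        return self.geometry.area

    @property
    def centroid(self) -> Point:
        return self.geometry.centroid


@dataclass(frozen=True)
class PoiPoint:
    """A daily-life point of interest; a kernel center of the life-heat surface."""

    id: str
    x: float
    y: float
    category: str

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class PopulationRaster:
    """Gridded residential population (people per cell, nonnegative reals)."""

    grid: GridSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != self.grid.shape:
            raise DataError(
                f"population array shape {counts.shape} does not match grid {self.grid.shape}"
            )
        if np.any(counts < 0):
            raise DataError("population counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DemandUnit:
    """A polygonal population-accounting unit; its centroid stands in for its residents."""

    id: str
    geometry: Polygon
    population: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise DataError(f"demand unit {self.id!r} has negative population")
        if not self.geometry.is_valid or self.geometry.is_empty:
            raise DataError(f"demand unit {self.id!r} has invalid or empty geometry")

    @property
    def centroid(self) -> Point:
        return self.geometry.centroid


def as_polygon(geom: BaseGeometry) -> Polygon:
    """Coerce to a Polygon, taking the largest part of a multi-geometry."""
    if isinstance(geom, Polygon):
        return geom
    if geom.geom_type == "MultiPolygon":
        return max(geom.geoms, key=lambda g: g.area)
    raise DataError(f"expected polygonal geometry, got {geom.geom_type}")
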