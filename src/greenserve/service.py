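"""Green-space service layers: cooling, recreation and disaster shelter.

Each service function maps a green patch to a service radius, buffers the
patch boundary outward by that radius, and dissolves the buffers into a
service footprint clipped to the study area:

* cooling — radius logarithmic in patch area, y = 53.668 ln x - 448.33
  (x in m2, y in m; negative values clamp to 0, so patches under ~4.25e3 m2
  cool only their own footprint);
* recreation — park patches only, walk-based disks at 420 m (< 5 min at
  5 km/h) and 1250 m (15-minute life circle); the scales are cumulative,
  the 1250 m layer being the full 0–1250 m disk;
* disaster shelter — piecewise-constant radii by size class (0.5–1 ha:
  500 m, 1–10 ha: 1 km, 10–50 ha: 2 km, >=50 ha: 3 km; protective buffers
  over 0.5 ha: 300 m).

A layer also records its overlap region (covered by two or more individual
buffers before dissolving) and supports per-heat-zone coverage statistics
and the composite space jointly served by all three functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ConfigError, DataError
from .heat import HeatZoneMap
from .rounding import ratio_percent, round_half_up
from .types import BUFFER, PARK, GreenSpacePolygon, StudyArea

import pandas as pd

WALK_SPEED_KMH = 5.0

#: Printed recreation scales in meters. 420 m is the table value for the
#: <5-minute walk (416.7 m exactly at 5 km/h), kept as printed.
RECREATION_SCALES = (420.0, 1250.0)

COOLING_A = 53.668
COOLING_B = 448.33

# Disaster-shelter radii by park size class, in (min_m2, max_m2, radius_m).
_DISASTER_PARK_TABLE = (
    (5e3, 1e4, 500.0),
    (1e4, 1e5, 1000.0),
    (1e5, 5e5, 2000.0),
    (5e5, float("inf"), 3000.0),
)
_DISASTER_BUFFER_MIN_M2 = 5e3
_DISASTER_BUFFER_RADIUS_M = 300.0


def cooling_radius(area_m2: float) -> float:
    """Maximum cooling (heat-island mitigation) radius of a patch, meters.

    Logarithmic in area with a zero-crossing at exp(448.33/53.668)
    ~ 4246 m2; smaller patches get radius 0 (footprint-only service).
    """
    if area_m2 <= 0:
        raise ConfigError(f"green area must be positive, got {area_m2}")
    return max(0.0, COOLING_A * math.log(area_m2) - COOLING_B)


def disaster_radius(category: str, area_m2: float) -> float:
    """Disaster-shelter service radius by category and size class, meters."""
    if area_m2 <= 0:
        raise ConfigError(f"green area must be positive, got {area_m2}")
    if category == PARK:
        for lo, hi, r in _DISASTER_PARK_TABLE:
            if lo <= area_m2 < hi:
                return r
        return 0.0  # below the smallest tabulated class
    if category == BUFFER:
        return _DISASTER_BUFFER_RADIUS_M if area_m2 >= _DISASTER_BUFFER_MIN_M2 else 0.0
    raise ConfigError(f"unknown green-space category {category!r}")


def walking_distance_m(minutes: float, speed_kmh: float = WALK_SPEED_KMH) -> float:
    """Distance walked in ``minutes`` at ``speed_kmh`` (15 min -> 1250 m)."""
    if minutes < 0:
        raise ConfigError("walking time must be nonnegative")
    return speed_kmh * 1000.0 / 60.0 * minutes


def recreation_radii() -> tuple[float, float]:
    """The two recreation scales (420 m, 1250 m)."""
    return RECREATION_SCALES


@dataclass(frozen=True)
class RadiusRule:
    """A service function: which categories it serves and at what radius."""

    tag: str
    radius_for: Callable[[str, float], float]
    eligible_categories: tuple[str, ...]

    def radius(self, category: str, area_m2: float) -> float:
        r = self.radius_for(category, area_m2)
        if r < 0:
            raise DataError(f"rule {self.tag} produced a negative radius")
        return r


def cooling_rule() -> RadiusRule:
    return RadiusRule(
        tag="cooling",
        radius_for=lambda cat, a: cooling_radius(a),
        eligible_categories=(PARK, BUFFER),
    )


def recreation_rule(scale_m: float = 1250.0) -> RadiusRule:
    if scale_m not in RECREATION_SCALES:
        raise ConfigError(f"recreation scale must be one of {RECREATION_SCALES}")
    return RadiusRule(
        tag=f"recreation_{int(scale_m)}",
        radius_for=lambda cat, a: float(scale_m),
        eligible_categories=(PARK,),  # protective buffers provide no recreation
    )


def disaster_rule() -> RadiusRule:
    return RadiusRule(
        tag="disaster",
        radius_for=disaster_radius,
        eligible_categories=(PARK, BUFFER),
    )


@dataclass(frozen=True)
class ServiceLayer:
    """One service function's footprint over the study area."""

    tag: str
    source_ids: tuple[str, ...]
    buffers: tuple[BaseGeometry, ...]  # per-source buffered shapes, unclipped
    union: BaseGeometry  # dissolved service space, clipped to study area
    overlap: BaseGeometry  # covered by >= 2 buffers, clipped

    @property
    def union_km2(self) -> float:
        return self.union.area / 1e6

    @property
    def overlap_km2(self) -> float:
        return self.overlap.area / 1e6


def build_service_layer(
    greens: list[GreenSpacePolygon], rule: RadiusRule, area: StudyArea
) -> ServiceLayer:
    """Buffer every eligible source outward and dissolve into one layer.

    Buffers are measured from the polygon boundary (shapely's polygon
    buffer), so the source footprint is always inside its own buffer and
    counts as served even at radius 0.
    """
    buffers: list[BaseGeometry] = []
    ids: list[str] = []
    for g in greens:
        if g.category not in rule.eligible_categories:
            continue
        if not g.geometry.is_valid:
            raise DataError(f"invalid geometry for green space {g.id!r}")
        r = rule.radius(g.category, g.area_m2)
        buffers.append(g.geometry.buffer(r) if r > 0 else g.geometry)
        ids.append(g.id)
    if not buffers:
        empty = shapely.Polygon()
        return ServiceLayer(tag=rule.tag, source_ids=(), buffers=(), union=empty, overlap=empty)
    union = unary_union(buffers).intersection(area.boundary)
    pair_overlaps = [
        buffers[i].intersection(buffers[j])
        for i in range(len(buffers))
        for j in range(i + 1, len(buffers))
        if buffers[i].intersects(buffers[j])
    ]
    overlap = (
        unary_union(pair_overlaps).intersection(area.boundary)
        if pair_overlaps
        else shapely.Polygon()
    )
    return ServiceLayer(
        tag=rule.tag,
        source_ids=tuple(ids),
        buffers=tuple(buffers),
        union=union,
        overlap=overlap,
    )


def zone_polygons(zones: HeatZoneMap) -> list[BaseGeometry]:
    """Exact polygon of each heat zone (union of its grid cells)."""
    g = zones.grid
    polys = []
    for level in range(zones.n_classes):
        rows, cols = np.nonzero(zones.zone_mask(level))
        if rows.size == 0:
            polys.append(shapely.Polygon())
            continue
        x0 = g.xmin + cols * g.cell_size
        y1 = g.ymax - rows * g.cell_size
        boxes = shapely.box(x0, y1 - g.cell_size, x0 + g.cell_size, y1)
        polys.append(shapely.coverage_union_all(boxes))
    return polys


def coverage_by_zone(layer: ServiceLayer, zones: HeatZoneMap) -> pd.DataFrame:
    """Served area and coverage ratio of the layer within each heat zone.

    Areas in km2 (3 decimals), ratios as percent (2 decimals, half-up);
    the Total row uses the unrounded sums.
    """
    rows = []
    tot_area = tot_served = 0.0
    for name, poly in zip(zones.zone_names, zone_polygons(zones)):
        zone_area = poly.area
        served = poly.intersection(layer.union).area if zone_area > 0 else 0.0
        tot_area += zone_area
        tot_served += served
        rows.append(
            {
                "zone": name,
                "zone_area_km2": round_half_up(zone_area / 1e6, 3),
                "service_area_km2": round_half_up(served / 1e6, 3),
                "ratio_percent": ratio_percent(served, zone_area),
            }
        )
    rows.append(
        {
            "zone": "Total",
            "zone_area_km2": round_half_up(tot_area / 1e6, 3),
            "service_area_km2": round_half_up(tot_served / 1e6, 3),
            "ratio_percent": ratio_percent(tot_served, tot_area),
        }
    )
    return pd.DataFrame(rows)


def overlap_stats(layer: ServiceLayer) -> tuple[float, float]:
    """(overlap km2, overlap as percent of the service union, half-up)."""
    overlap_km2 = layer.overlap_km2
    union_km2 = layer.union_km2
    return round_half_up(overlap_km2, 3), ratio_percent(overlap_km2, union_km2)


def composite_service(layers: list[ServiceLayer], area: StudyArea) -> BaseGeometry:
    """The space enjoying all three services: intersection of the unions.

    Requires exactly the cooling, 1250 m recreation, and disaster layers.
    """
    required = {"cooling", "recreation_1250", "disaster"}
    tags = {layer.tag for layer in layers}
    if tags != required:
        raise ConfigError(f"composite needs layers {sorted(required)}, got {sorted(tags)}")
    geom: BaseGeometry = area.boundary
    for layer in layers:
        geom = geom.intersection(layer.union)
        if geom.is_empty:
            return shapely.Polygon()
    return geom
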