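"""Integrated supply-demand zoning.

Overlays three per-cell attributes — life-heat level (the five density
zones collapsed to low/medium/high), accessibility level (the per-unit
3-level class, inherited from the cell's demand unit) and whether the cell
enjoys all three green-space services — into 18 possible partition codes,
then merges them into six named areas keyed on the unit's supply flag
(A_i vs. the per-capita benchmark), the heat group and the service flag:

    supply >= demand, heat medium/high, enjoy      -> High-quality living area
    supply >= demand, heat low,         enjoy      -> Livable area
    supply <  demand, heat low,         not enjoy  -> Underdeveloped area
    supply >= demand, heat medium/high, not enjoy  -> Green space service blind area
    supply <  demand, heat medium/high, enjoy      -> Under supply and demand area
    supply <  demand, heat medium/high, not enjoy  -> Comprehensive blind area

The two combinations absent from that six-row table — (supply >= demand,
low heat, not enjoy) and (supply < demand, low heat, enjoy) — default to
the row differing in a single field: Green space service blind area and
Livable area respectively. The whole mapping is a plain dict and can be
overridden from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .access import ACCESS_LEVELS_3, AccessibilityResult
from .errors import ConfigError, DataError
from .grids import GridSpec
from .heat import HeatZoneMap
from .rounding import ratio_percent, round_half_up
from .types import DemandUnit

HEAT_LEVELS_3 = ("low", "medium", "high")

#: Five density zones -> three overlay levels.
HEAT_COLLAPSE = {
    "Cold": "low",
    "Sub-Cold": "low",
    "Not-Significant": "medium",
    "Sub-Hot": "high",
    "Hot": "high",
}

ZONE_NAMES_6 = (
    "High-quality living area",
    "Livable area",
    "Underdeveloped area",
    "Green space service blind area",
    "Under supply and demand area",
    "Comprehensive blind area",
)

# keys: (supply_ge_demand, heat in {"low", "medhigh"}, enjoys_service)
DEFAULT_MERGE_MAPPING: dict[tuple[bool, str, bool], str] = {
    (True, "medhigh", True): "High-quality living area",
    (True, "low", True): "Livable area",
    (False, "low", False): "Underdeveloped area",
    (True, "medhigh", False): "Green space service blind area",
    (False, "medhigh", True): "Under supply and demand area",
    (False, "medhigh", False): "Comprehensive blind area",
    # combinations absent from the six-row table (documented defaults):
    (True, "low", False): "Green space service blind area",
    (False, "low", True): "Livable area",
}


@dataclass(frozen=True)
class PartitionGrid:
    """Per-cell overlay attributes on the heat grid.

    ``heat3``/``access3`` index into the 3-level scales; ``service`` is the
    enjoy flag; ``supply`` the unit-level supply>=demand flag; cells outside
    the study area are masked out.
    """

    grid: GridSpec
    heat3: np.ndarray  # int 0..2, -1 outside
    access3: np.ndarray  # int 0..2
    service: np.ndarray  # bool
    supply: np.ndarray  # bool
    valid: np.ndarray  # bool mask of study-area cells

    def code_histogram(self) -> pd.DataFrame:
        """Counts of the 18 (heat, access, service) partition codes."""
        rows = []
        for hi, hname in enumerate(HEAT_LEVELS_3):
            for ai, aname in enumerate(ACCESS_LEVELS_3):
                for flag in (True, False):
                    n = int(
                        (
                            self.valid
                            & (self.heat3 == hi)
                            & (self.access3 == ai)
                            & (self.service == flag)
                        ).sum()
                    )
                    rows.append(
                        {
                            "heat": hname,
                            "access": aname,
                            "service": "enjoy" if flag else "not-enjoy",
                            "cells": n,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntegratedZoneMap:
    """Named six-area map on the heat grid."""

    grid: GridSpec
    labels: np.ndarray  # int index into zone_names, -1 outside
    zone_names: tuple[str, ...] = ZONE_NAMES_6

    def zone_area_m2(self, idx: int) -> float:
        return float((self.labels == idx).sum()) * self.grid.cell_area_m2


def partition(
    zones: HeatZoneMap,
    access: AccessibilityResult,
    units: list[DemandUnit],
    composite: BaseGeometry,
    heat_collapse: dict[str, str] | None = None,
) -> PartitionGrid:
    """Assign every heat-grid cell its (heat, access, service) code.

    A cell inherits accessibility class and supply flag from the demand
    unit containing its center (nearest unit for centers on shared edges
    clipped away by floating point).
    """
    if heat_collapse is None:
        heat_collapse = HEAT_COLLAPSE
    if len(units) != len(access.table):
        raise DataError("accessibility table does not match the demand-unit list")
    g = zones.grid
    X, Y = g.cell_centers()
    valid = zones.labels >= 0

    heat3 = np.full(g.shape, -1, dtype=int)
    for level, name in enumerate(zones.zone_names):
        try:
            collapsed = heat_collapse[name]
        except KeyError:
            raise ConfigError(f"heat collapse mapping lacks zone {name!r}") from None
        heat3[zones.labels == level] = HEAT_LEVELS_3.index(collapsed)

    # unit lookup by containment, nearest as fallback
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    tree = shapely.STRtree([u.geometry for u in units])
    unit_idx = np.full(len(pts), -1, dtype=int)
    inside_i, unit_i = tree.query(pts, predicate="within")
    # keep the first (lowest-index) unit for any duplicated point
    seen = np.full(len(pts), False)
    for p_i, u_i in zip(inside_i, unit_i):
        if not seen[p_i]:
            unit_idx[p_i] = u_i
            seen[p_i] = True
    missing = np.nonzero(unit_idx < 0)[0]
    if missing.size:
        nearest = tree.nearest(pts[missing])
        unit_idx[missing] = nearest

    level3_codes = np.array(
        [ACCESS_LEVELS_3.index(s) for s in access.table["level3"]], dtype=int
    )
    supply_flags = access.table["supply_ge_demand"].to_numpy()
    access3 = level3_codes[unit_idx].reshape(g.shape)
    supply = supply_flags[unit_idx].reshape(g.shape)
    service = shapely.contains_xy(composite, X.ravel(), Y.ravel()).reshape(g.shape)
    return PartitionGrid(
        grid=g, heat3=heat3, access3=access3, service=service, supply=supply, valid=valid
    )


def _validate_mapping(mapping: dict[tuple[bool, str, bool], str]) -> None:
    for supply in (True, False):
        for heat in ("low", "medhigh"):
            for service in (True, False):
                key = (supply, heat, service)
                if key not in mapping:
                    raise ConfigError(f"merge mapping is not total: missing {key}")
                if mapping[key] not in ZONE_NAMES_6:
                    raise ConfigError(f"unknown zone name {mapping[key]!r} in mapping")


def merge_partitions(
    parts: PartitionGrid,
    mapping: dict[tuple[bool, str, bool], str] | None = None,
) -> IntegratedZoneMap:
    """Merge partition codes into the six named areas.

    The mapping must be total over (supply flag, heat group, service flag);
    heat levels medium and high share the "medhigh" group.
    """
    if mapping is None:
        mapping = DEFAULT_MERGE_MAPPING
    _validate_mapping(mapping)
    labels = np.full(parts.grid.shape, -1, dtype=int)
    heat_group = np.where(parts.heat3 == 0, "low", "medhigh")
    for supply in (True, False):
        for hg in ("low", "medhigh"):
            for service in (True, False):
                zone_idx = ZONE_NAMES_6.index(mapping[(supply, hg, service)])
                sel = (
                    parts.valid
                    & (parts.supply == supply)
                    & (heat_group == hg)
                    & (parts.service == service)
                )
                labels[sel] = zone_idx
    return IntegratedZoneMap(grid=parts.grid, labels=labels)


def zone_report(zmap: IntegratedZoneMap) -> pd.DataFrame:
    """Area (km2) and percent per named area; empty zones keep a 0.00% row."""
    areas = np.array([zmap.zone_area_m2(i) for i in range(len(zmap.zone_names))]) / 1e6
    total = areas.sum()
    rows = [
        {
            "zone": name,
            "area_km2": round_half_up(a, 3),
            "percent": ratio_percent(a, total),
        }
        for name, a in zip(zmap.zone_names, areas)
    ]
    rows.append({"zone": "Total", "area_km2": round_half_up(total, 3), "percent": 100.00})
    return pd.DataFrame(rows)


def mapping_from_dicts(rows: list[dict]) -> dict[tuple[bool, str, bool], str]:
    """Build a merge mapping from YAML-friendly records.

    Each record: ``{supply: ">="|"<", heat: "low"|"medhigh", service:
    "enjoy"|"not-enjoy", zone: <name>}``.
    """
    mapping: dict[tuple[bool, str, bool], str] = {}
    for row in rows:
        try:
            key = (row["supply"] == ">=", row["heat"], row["service"] == "enjoy")
            mapping[key] = row["zone"]
        except KeyError as exc:
            raise ConfigError(f"mapping record missing field: {exc}") from None
    _validate_mapping(mapping)
    return mapping


def mapping_to_dicts(mapping: dict[tuple[bool, str, bool], str]) -> list[dict]:
    return [
        {
            "supply": ">=" if supply else "<",
            "heat": heat,
            "service": "enjoy" if service else "not-enjoy",
            "zone": zone,
        }
        for (supply, heat, service), zone in mapping.items()
    ]
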