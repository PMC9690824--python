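"""Gaussian two-step floating catchment area (G2SFCA) accessibility.

Step 1 gives each park j a supply-demand ratio over its catchment,

    R_j = S_j / sum_{k : d_kj <= d0} G(d_kj) D_k,

with S_j the park area (m2), D_k the population of demand unit k, and G a
truncated Gaussian decay that equals 1 at distance 0 and 0 at the
threshold d0:

    G(d) = (exp(-(d/d0)^2 / 2) - exp(-1/2)) / (1 - exp(-1/2)),  d <= d0.

Step 2 sums distance-weighted ratios over each unit's catchment,

    A_i = sum_{j : d_ij <= d0} G(d_ij) R_j,

yielding park area per person (m2/person). d0 defaults to 1250 m, the
15-minute walking life circle. Distances are Euclidean between unit
centroids and park geometric centroids; the distance backend is a single
function so a network metric can be swapped in.

The defining conservation law — sum_i D_i A_i equals the total area of all
served parks — holds exactly because both steps use the same distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .heat import class_breaks
from .types import PARK, DemandUnit, GreenSpacePolygon

ACCESS_LEVELS_4 = ("low", "medium", "mid-high", "high")
ACCESS_LEVELS_3 = ("low", "medium", "high")

#: Collapse of the four accessibility classes to the three overlay levels.
COLLAPSE_4_TO_3 = {"low": "low", "medium": "medium", "mid-high": "high", "high": "high"}


@dataclass(frozen=True)
class DecayParams:
    """Catchment threshold d0 in meters (15-min walk by default)."""

    d0: float = 1250.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ConfigError(f"d0 must be positive, got {self.d0}")


def gaussian_decay(d, p: DecayParams = DecayParams()):
    """Truncated, rescaled Gaussian weight in [0, 1]; 0 beyond d0.

    Accepts scalars or arrays; raises on negative distance.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ConfigError("distance must be nonnegative")
    e_half = math.exp(-0.5)
    w = (np.exp(-0.5 * (d_arr / p.d0) ** 2) - e_half) / (1.0 - e_half)
    w = np.where(d_arr <= p.d0, w, 0.0)
    return float(w) if np.isscalar(d) else w


def euclidean_distances(units: list[DemandUnit], parks: list[GreenSpacePolygon]) -> np.ndarray:
    """(n_units, n_parks) straight-line centroid-to-centroid distances, meters."""
    if not units or not parks:
        return np.zeros((len(units), len(parks)))
    uc = np.array([[u.centroid.x, u.centroid.y] for u in units])
    pc = np.array([[g.centroid.x, g.centroid.y] for g in parks])
    return np.hypot(uc[:, None, 0] - pc[None, :, 0], uc[:, None, 1] - pc[None, :, 1])


def _park_subset(greens: list[GreenSpacePolygon]) -> list[GreenSpacePolygon]:
    return [g for g in greens if g.category == PARK]


def supply_demand_ratios(
    greens: list[GreenSpacePolygon],
    units: list[DemandUnit],
    p: DecayParams = DecayParams(),
    distances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Step 1: per-park supply-demand ratio R_j (m2 per person-weight).

    Only park-category green space supplies recreation-style access.
    A park whose catchment holds no weighted demand is flagged unserved
    (``served=False``, R_j = NaN) and contributes nothing downstream.
    """
    parks = _park_subset(greens)
    if distances is None:
        distances = euclidean_distances(units, parks)
    elif distances.shape != (len(units), len(parks)):
        raise DataError("distance matrix shape does not match units x parks")
    pops = np.array([u.population for u in units])
    weights = gaussian_decay(distances, p) if len(units) and len(parks) else distances
    demand = (weights * pops[:, None]).sum(axis=0) if len(parks) else np.zeros(0)
    areas = np.array([g.area_m2 for g in parks])
    served = demand > 0
    ratios = np.full(len(parks), np.nan)
    ratios[served] = areas[served] / demand[served]
    return pd.DataFrame(
        {
            "park_id": [g.id for g in parks],
            "area_m2": areas,
            "weighted_demand": demand,
            "R": ratios,
            "served": served,
        }
    )


@dataclass(frozen=True)
class AccessibilityResult:
    """Per-unit accessibility with class labels and the supply flag."""

    table: pd.DataFrame  # unit_id, population, A, level4, level3, supply_ge_demand
    ratios: pd.DataFrame  # the step-1 table
    benchmark_m2_per_capita: float
    params: DecayParams

    def level3_of(self, unit_id: str) -> str:
        row = self.table.loc[self.table["unit_id"] == unit_id]
        return str(row["level3"].iloc[0])


def accessibility_values(
    units: list[DemandUnit],
    greens: list[GreenSpacePolygon],
    ratios: pd.DataFrame,
    p: DecayParams = DecayParams(),
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Step 2: A_i for every demand unit (m2 per person)."""
    parks = _park_subset(greens)
    if len(ratios) != len(parks):
        raise DataError("ratios table does not match the park set")
    if distances is None:
        distances = euclidean_distances(units, parks)
    if not len(units) or not len(parks):
        return np.zeros(len(units))
    weights = gaussian_decay(distances, p)
    r = np.where(ratios["served"].to_numpy(), ratios["R"].to_numpy(), 0.0)
    return weights @ r


def per_capita_benchmark(
    greens: list[GreenSpacePolygon], units: list[DemandUnit]
) -> float:
    """Citywide park area per person: the supply-sufficiency benchmark."""
    total_pop = sum(u.population for u in units)
    if total_pop <= 0:
        raise DataError("total population must be positive for the per-capita benchmark")
    return sum(g.area_m2 for g in _park_subset(greens)) / total_pop


def classify_accessibility(
    values: np.ndarray, method: str = "quantile", k: int = 4
) -> tuple[list[str], list[str]]:
    """Ordered labels for A_i plus the 3-level collapse used by the overlay.

    Monotone: a higher A_i never gets a lower label. Raises when the
    values carry fewer distinct levels than classes.
    """
    if k != len(ACCESS_LEVELS_4):
        raise ConfigError("accessibility classification uses 4 classes")
    values = np.asarray(values, dtype=float)
    breaks = class_breaks(values, method, k)  # raises on degenerate input
    idx = np.clip(np.searchsorted(breaks, values, side="left"), 0, k - 1)
    level4 = [ACCESS_LEVELS_4[i] for i in idx]
    level3 = [COLLAPSE_4_TO_3[name] for name in level4]
    return level4, level3


def evaluate_accessibility(
    greens: list[GreenSpacePolygon],
    units: list[DemandUnit],
    p: DecayParams = DecayParams(),
    method: str = "quantile",
    distances: np.ndarray | None = None,
) -> AccessibilityResult:
    """Full G2SFCA evaluation: ratios, A_i, classes, supply flag, benchmark."""
    ratios = supply_demand_ratios(greens, units, p, distances=distances)
    A = accessibility_values(units, greens, ratios, p, distances=distances)
    benchmark = per_capita_benchmark(greens, units)
    try:
        level4, level3 = classify_accessibility(A, method=method)
    except DataError:
        # degenerate surface (e.g. no parks): everything is low access
        level4 = ["low"] * len(units)
        level3 = ["low"] * len(units)
    table = pd.DataFrame(
        {
            "unit_id": [u.id for u in units],
            "population": [u.population for u in units],
            "A_m2_per_capita": A,
            "level4": level4,
            "level3": level3,
            "supply_ge_demand": A >= benchmark,
        }
    )
    return AccessibilityResult(
        table=table, ratios=ratios, benchmark_m2_per_capita=benchmark, params=p
    )
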