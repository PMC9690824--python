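"""Residents' life-heat surface and density zoning.

The heat surface is the kernel density of daily-life POIs. The default
kernel is the finite-support parabolic form

    f(s) = sum over POIs c_i with ||s - c_i|| <= h of
           (1 / (pi h^2)) * (1 - ||s - c_i||^2 / h^2)

which integrates to 1/2 over its support disk (it is an Epanechnikov-type
profile without the quartic normalizer; :func:`kernel_mass` documents the
constant). The widely used quartic kernel, with unit mass, is available
behind ``kernel="quartic"``.

The surface is sliced into five ordered density zones (Cold, Sub-Cold,
Not-Significant, Sub-Hot, Hot) by natural breaks (Fisher-Jenks), quantiles
or equal intervals, and summarized as an area/percentage table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .errors import ConfigError, DataError
from .grids import GridSpec
from .rounding import ratio_percent, round_half_up
from .types import PoiPoint

ZONE_NAMES = ("Cold", "Sub-Cold", "Not-Significant", "Sub-Hot", "Hot")

KERNELS = ("printed", "quartic")


@dataclass(frozen=True)
class HeatSurface:
    """Kernel-density values on a regular grid; bandwidth in meters."""

    grid: GridSpec
    values: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise DataError("heat values shape does not match grid")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class HeatZoneMap:
    """Ordered density-zone labels per cell (0 = coldest)."""

    grid: GridSpec
    labels: np.ndarray  # int, -1 outside the study area
    breaks: tuple[float, ...]
    zone_names: tuple[str, ...] = ZONE_NAMES

    @property
    def n_classes(self) -> int:
        return len(self.zone_names)

    def zone_mask(self, level: int) -> np.ndarray:
        return self.labels == level

    def zone_area_m2(self, level: int) -> float:
        return float(self.zone_mask(level).sum()) * self.grid.cell_area_m2


def _kernel_profile(d2: np.ndarray, h: float, kernel: str) -> np.ndarray:
    u2 = d2 / (h * h)
    base = 1.0 - u2
    base[base < 0] = 0.0
    if kernel == "printed":
        return base / (np.pi * h * h)
    return 3.0 / (np.pi * h * h) * base * base


def kde_surface(
    pois: list[PoiPoint],
    h: float,
    grid: GridSpec,
    kernel: str = "printed",
    chunk_rows: int = 32,
) -> HeatSurface:
    """Evaluate the POI kernel density at every cell center.

    Finite support: cells farther than ``h`` from every POI are exactly 0,
    and the surface is the plain sum of per-POI kernels (superposition).
    """
    if h <= 0:
        raise ConfigError(f"bandwidth must be positive, got {h}")
    if kernel not in KERNELS:
        raise ConfigError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    X, Y = grid.cell_centers()
    values = np.zeros(grid.shape)
    if pois:
        px = np.array([p.x for p in pois])
        py = np.array([p.y for p in pois])
        for r0 in range(0, grid.nrows, chunk_rows):
            r1 = min(r0 + chunk_rows, grid.nrows)
            dx = X[r0:r1, :, None] - px[None, None, :]
            dy = Y[r0:r1, :, None] - py[None, None, :]
            values[r0:r1] = _kernel_profile(dx * dx + dy * dy, h, kernel).sum(axis=2)
    return HeatSurface(grid=grid, values=values, bandwidth=h)


def kde_at_points(
    pois: list[PoiPoint], h: float, x: np.ndarray, y: np.ndarray, kernel: str = "printed"
) -> np.ndarray:
    """Kernel density evaluated at arbitrary points (same sum as the surface)."""
    if h <= 0:
        raise ConfigError(f"bandwidth must be positive, got {h}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.zeros(x.shape)
    for p in pois:
        d2 = (x - p.x) ** 2 + (y - p.y) ** 2
        out += _kernel_profile(d2, h, kernel)
    return out


def kernel_mass(h: float, kernel: str = "printed") -> float:
    """Numerical integral of the kernel over its support disk.

    The default parabolic profile integrates to exactly 1/2 for every
    bandwidth; the quartic option integrates to 1. Computed by quadrature
    rather than asserted, so the constant is a property of the code path
    actually used by :func:`kde_surface`.
    """
    if h <= 0:
        raise ConfigError(f"bandwidth must be positive, got {h}")

    def integrand(r: float) -> float:
        return 2.0 * np.pi * r * float(_kernel_profile(np.array([r * r]), h, kernel)[0])

    mass, _ = integrate.quad(integrand, 0.0, h)
    return mass


def _fisher_jenks_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Optimal 1-D partition into k classes minimizing within-class SSD.

    Dynamic program over sorted values using prefix sums; O(k n^2). Inputs
    larger than ``_MAX_N`` are deterministically thinned (evenly spaced
    order statistics) before the DP.
    """
    _MAX_N = 2500
    v = np.sort(values)
    if v.size > _MAX_N:
        idx = np.linspace(0, v.size - 1, _MAX_N).round().astype(int)
        v = v[idx]
    n = v.size
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csum2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: np.ndarray, j: int | np.ndarray) -> np.ndarray:
        # within-class sum of squared deviations of v[i:j]
        cnt = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / cnt

    cost = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[1, 1:] = ssd(np.zeros(n, dtype=int), np.arange(1, n + 1))
    for m in range(2, k + 1):
        for j in range(m, n + 1):
            i = np.arange(m - 1, j)
            cand = cost[m - 1, i] + ssd(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            cut[m, j] = i[best]
    # recover class boundaries as the last value of each lower class
    bounds = []
    j = n
    for m in range(k, 1, -1):
        i = cut[m, j]
        bounds.append(v[i - 1])
        j = i
    return np.array(bounds[::-1])


def class_breaks(values: np.ndarray, method: str, k: int) -> np.ndarray:
    """k-1 interior break values (a cell with value <= break[i] is in class <= i)."""
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < k:
        raise DataError(
            f"cannot form {k} classes from {np.unique(values).size} distinct values"
        )
    if method == "equal_interval":
        lo, hi = values.min(), values.max()
        return lo + (hi - lo) * np.arange(1, k) / k
    if method == "quantile":
        return np.quantile(values, np.arange(1, k) / k)
    if method == "jenks":
        return _fisher_jenks_breaks(values, k)
    raise ConfigError(f"unknown classification method {method!r}")


def classify_heat(
    surface: HeatSurface,
    method: str = "jenks",
    k: int = 5,
    mask: np.ndarray | None = None,
    zone_names: tuple[str, ...] | None = None,
) -> HeatZoneMap:
    """Slice the heat surface into k ordered zones (0 coldest .. k-1 hottest).

    ``mask`` restricts classification to study-area cells; cells outside
    get label -1. Labels are by construction monotone in the cell value.
    """
    if zone_names is None:
        zone_names = ZONE_NAMES if k == 5 else tuple(f"class-{i}" for i in range(k))
    if len(zone_names) != k:
        raise ConfigError("zone_names length must equal k")
    if mask is None:
        mask = np.ones(surface.grid.shape, dtype=bool)
    vals = surface.values[mask]
    if vals.size == 0:
        raise DataError("no cells to classify")
    breaks = class_breaks(vals, method, k)
    labels = np.full(surface.grid.shape, -1, dtype=int)
    labels[mask] = np.searchsorted(breaks, surface.values[mask], side="left")
    labels[mask] = np.clip(labels[mask], 0, k - 1)
    return HeatZoneMap(
        grid=surface.grid, labels=labels, breaks=tuple(float(b) for b in breaks),
        zone_names=zone_names,
    )


def zone_area_table(zones: HeatZoneMap) -> pd.DataFrame:
    """Per-zone area (km2) and percent of the classified total, plus a total row.

    Percentages are round-half-up at 2 decimals; areas at 3 decimals.
    """
    areas = np.array([zones.zone_area_m2(i) for i in range(zones.n_classes)]) / 1e6
    total = areas.sum()
    rows = [
        {
            "zone": name,
            "area_km2": round_half_up(a, 3),
            "percent": ratio_percent(a, total),
        }
        for name, a in zip(zones.zone_names, areas)
    ]
    rows.append({"zone": "Total", "area_km2": round_half_up(total, 3), "percent": 100.00})
    return pd.DataFrame(rows)
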