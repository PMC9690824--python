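"""Seeded synthetic city generator.

Builds a compact study area with the statistical structure the analysis
assumes: green patches spanning the disaster-table size classes, points of
interest clustered on an "old town" core with density decaying irregularly
outward, population concentrated where the POIs are, and a tessellation of
demand units carrying that population. Every stage draws from its own
seeded generator, so one config yields bit-identical output forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .errors import ConfigError, DataError
from .grids import GridSpec
from .types import BUFFER, PARK, DemandUnit, GreenSpacePolygon, PoiPoint, PopulationRaster, StudyArea

# 19 daily-life POI classes (navigation-map style taxonomy).
POI_CATEGORIES = (
    "catering", "shopping", "life_service", "accommodation", "public_facility",
    "medical", "education", "finance", "sport_leisure", "culture",
    "government", "transport", "auto_service", "business_office", "science_tech",
    "scenic_spot", "telecom", "market", "community_service",
)

# Park size classes of the disaster-service table, in m2 (0.5-1, 1-10,
# 10-50, >50 hectares). The last class is open above.
PARK_SIZE_CLASSES = ((5e3, 1e4), (1e4, 1e5), (1e5, 5e5), (5e5, float("inf")))

# Stage tags used to derive independent deterministic RNG streams.
_STAGES = {"area": 0, "greens": 1, "pois": 2, "population": 3, "units": 4}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic city.

    Defaults mirror the study conditions of the method: a ~45.5 km2
    built-up extent, 1294 deduplicated POIs, a 100 m population raster and
    233 demand units.
    """

    seed: int = 0
    extent_m: tuple[float, float] = (7000.0, 6500.0)
    n_parks: int = 30
    n_buffers: int = 8
    park_area_range_m2: tuple[float, float] = (5e3, 1e6)
    n_poi: int = 1294
    poi_cluster_centers: tuple[tuple[float, float, float, float], ...] | None = None
    poi_background_weight: float = 0.15
    population_total: int = 160_000
    pop_background_weight: float = 0.2
    pop_cell_m: float = 100.0
    demand_unit_count: int = 233
    tessellation: str = "grid"  # or "voronoi"
    area_shape: str = "rectangle"  # or "irregular"

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ConfigError("extent_m must be strictly positive")
        lo, hi = self.park_area_range_m2
        if not lo < hi:
            raise ConfigError("park_area_range_m2 min must be < max")
        for name in ("n_parks", "n_buffers", "n_poi", "demand_unit_count", "population_total"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.pop_cell_m <= 0:
            raise ConfigError("pop_cell_m must be positive")
        if self.tessellation not in ("grid", "voronoi"):
            raise ConfigError(f"unknown tessellation {self.tessellation!r}")
        if self.area_shape not in ("rectangle", "irregular"):
            raise ConfigError(f"unknown area_shape {self.area_shape!r}")

    def default_clusters(self) -> tuple[tuple[float, float, float, float], ...]:
        """(x, y, weight, spread_m) mixture; heaviest component = old-town core."""
        if self.poi_cluster_centers is not None:
            return self.poi_cluster_centers
        w, h = self.extent_m
        return (
            (0.36 * w, 0.42 * h, 0.55, 500.0),   # old town core
            (0.55 * w, 0.58 * h, 0.30, 900.0),   # newer district
            (0.75 * w, 0.72 * h, 0.15, 1300.0),  # outer sub-center
        )


def _rng(cfg: SynthConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGES[stage], cfg.seed])


def generate_study_area(cfg: SynthConfig) -> StudyArea:
    """Rectangle of the configured extent, or a seeded irregular polygon."""
    w, h = cfg.extent_m
    if cfg.area_shape == "rectangle":
        return StudyArea(boundary=box(0.0, 0.0, w, h))
    rng = _rng(cfg, "area")
    # Star-shaped polygon: smooth radial jitter around the extent center.
    n = 24
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    jitter = rng.uniform(-1.0, 1.0, n)
    # three-point moving average keeps the outline smooth and simple
    jitter = (jitter + np.roll(jitter, 1) + np.roll(jitter, -1)) / 3.0
    rx = 0.5 * w * (0.85 + 0.15 * jitter)
    ry = 0.5 * h * (0.85 + 0.15 * jitter)
    pts = np.column_stack([0.5 * w + rx * np.cos(theta), 0.5 * h + ry * np.sin(theta)])
    return StudyArea(boundary=Polygon(pts))


def _park_classes_in_range(cfg: SynthConfig) -> list[tuple[float, float]]:
    lo, hi = cfg.park_area_range_m2
    out = []
    for clo, chi in PARK_SIZE_CLASSES:
        a, b = max(lo, clo), min(hi, chi)
        if a < b:
            out.append((a, b))
    return out


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _place_rect(
    rng: np.random.Generator,
    area: StudyArea,
    width: float,
    height: float,
    existing: list[Polygon],
    tries: int = 50,
) -> Polygon:
    """Axis-aligned rectangle inside the area bounds, avoiding overlap when possible."""
    xmin, ymin, xmax, ymax = area.boundary.bounds
    last = None
    for _ in range(tries):
        x = rng.uniform(xmin, max(xmin, xmax - width))
        y = rng.uniform(ymin, max(ymin, ymax - height))
        cand = box(x, y, x + width, y + height)
        last = cand
        if all(not cand.intersects(g) for g in existing):
            return cand
    return last


def generate_green_spaces(
    cfg: SynthConfig, area: StudyArea, strict: bool = False
) -> list[GreenSpacePolygon]:
    """Parks with log-uniform areas spanning the size classes, plus elongated buffers.

    The first draws are stratified one-per-size-class (so every disaster
    class that the configured range permits is exercised); the remainder are
    log-uniform over the full range. Protective buffers are high-aspect
    strips, emulating green belts along rivers and roads.
    """
    rng = _rng(cfg, "greens")
    classes = _park_classes_in_range(cfg)
    if strict and (not classes or cfg.n_parks < len(classes)):
        raise ConfigError(
            f"cannot cover {len(classes)} park size classes with n_parks={cfg.n_parks}"
        )
    lo, hi = cfg.park_area_range_m2
    greens: list[GreenSpacePolygon] = []
    shapes: list[Polygon] = []
    for i in range(cfg.n_parks):
        if i < len(classes):
            clo, chi = classes[i]
            target = _log_uniform(rng, clo, min(chi, hi))
        else:
            target = _log_uniform(rng, lo, hi)
        aspect = rng.uniform(1.0, 2.5)
        w_p = float(np.sqrt(target * aspect))
        h_p = float(np.sqrt(target / aspect))
        geom = _place_rect(rng, area, w_p, h_p, shapes)
        geom = geom.intersection(area.boundary)
        if geom.is_empty:
            continue
        shapes.append(geom)
        greens.append(GreenSpacePolygon(id=f"park-{i:03d}", geometry=geom, category=PARK))
    for i in range(cfg.n_buffers):
        length = rng.uniform(1500.0, 4000.0)
        width = rng.uniform(30.0, 80.0)
        if rng.uniform() < 0.5:
            w_b, h_b = length, width
        else:
            w_b, h_b = width, length
        geom = _place_rect(rng, area, w_b, h_b, shapes)
        geom = geom.intersection(area.boundary)
        if geom.is_empty:
            continue
        shapes.append(geom)
        greens.append(GreenSpacePolygon(id=f"buffer-{i:03d}", geometry=geom, category=BUFFER))
    return greens


def generate_pois(cfg: SynthConfig, area: StudyArea) -> list[PoiPoint]:
    """Mixture of isotropic clusters plus a uniform background, deduplicated."""
    rng = _rng(cfg, "pois")
    clusters = cfg.default_clusters()
    for cx, cy, _, _ in clusters:
        if not area.boundary.covers(Point(cx, cy)):
            raise ConfigError(f"POI cluster center ({cx}, {cy}) lies outside the study area")
    weights = np.array([c[2] for c in clusters], dtype=float)
    weights = weights / weights.sum() * (1.0 - cfg.poi_background_weight)
    probs = np.append(weights, cfg.poi_background_weight)
    xmin, ymin, xmax, ymax = area.boundary.bounds

    seen: set[tuple[float, float, str]] = set()
    pois: list[PoiPoint] = []
    while len(pois) < cfg.n_poi:
        comp = int(rng.choice(len(probs), p=probs))
        if comp < len(clusters):
            cx, cy, _, spread = clusters[comp]
            x = float(rng.normal(cx, spread))
            y = float(rng.normal(cy, spread))
        else:
            x = float(rng.uniform(xmin, xmax))
            y = float(rng.uniform(ymin, ymax))
        if not area.boundary.covers(Point(x, y)):
            continue
        category = POI_CATEGORIES[int(rng.integers(len(POI_CATEGORIES)))]
        key = (round(x, 6), round(y, 6), category)
        if key in seen:  # exact duplicate location+type: the dedup rule
            continue
        seen.add(key)
        pois.append(PoiPoint(id=f"poi-{len(pois):04d}", x=x, y=y, category=category))
    return pois


def generate_population(
    cfg: SynthConfig, area: StudyArea, pois: list[PoiPoint]
) -> PopulationRaster:
    """Population proportional to blurred POI intensity plus a uniform floor.

    The raster is normalized so cells inside the study area sum exactly to
    ``population_total``; cells outside are zero.
    """
    xmin, ymin, xmax, ymax = area.boundary.bounds
    grid = GridSpec.from_bounds(xmin, ymin, xmax, ymax, cfg.pop_cell_m)
    X, Y = grid.cell_centers()
    inside = shapely.contains_xy(area.boundary, X.ravel(), Y.ravel()).reshape(grid.shape)

    if pois:
        hist = np.zeros(grid.shape)
        row, col = grid.index_of(
            np.array([p.x for p in pois]), np.array([p.y for p in pois])
        )
        np.add.at(hist, (row, col), 1.0)
        sigma_cells = 300.0 / cfg.pop_cell_m  # 300 m blur
        intensity = gaussian_filter(hist, sigma=sigma_cells)
        intensity[~inside] = 0.0
        if intensity.sum() > 0:
            intensity = intensity / intensity.sum()
        background = inside.astype(float) / inside.sum()
        density = (1.0 - cfg.pop_background_weight) * intensity + cfg.pop_background_weight * background
    else:
        density = inside.astype(float) / inside.sum()
    counts = density / density.sum() * cfg.population_total
    return PopulationRaster(grid=grid, counts=counts)


def _grid_tessellation(area: StudyArea, n: int) -> list[Polygon]:
    """Near-square exact-count tessellation: equal-height rows, each split
    into equal-width cells, with row column-counts differing by at most one
    (this handles any n, prime counts included)."""
    xmin, ymin, xmax, ymax = area.boundary.bounds
    w, h = xmax - xmin, ymax - ymin
    nrows = max(1, min(n, round(np.sqrt(n * h / w))))
    base, extra = divmod(n, nrows)
    if base == 0:
        nrows, base, extra = n, 1, 0
    row_h = h / nrows
    cells: list[Polygon] = []
    for r in range(nrows):
        ncols = base + (1 if r < extra else 0)
        col_w = w / ncols
        y0 = ymin + r * row_h
        for c in range(ncols):
            x0 = xmin + c * col_w
            cell = box(x0, y0, x0 + col_w, y0 + row_h).intersection(area.boundary)
            cells.append(cell)
    return cells


def _voronoi_tessellation(
    rng: np.random.Generator, area: StudyArea, n: int
) -> list[Polygon]:
    xmin, ymin, xmax, ymax = area.boundary.bounds
    seeds: list[Point] = []
    while len(seeds) < n:
        p = Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if area.boundary.covers(p):
            seeds.append(p)
    diagram = voronoi_diagram(MultiPoint(seeds), envelope=area.boundary)
    cells: list[Polygon] = [None] * n  # type: ignore[list-item]
    for region in diagram.geoms:
        for i, s in enumerate(seeds):
            if cells[i] is None and region.covers(s):
                cells[i] = region.intersection(area.boundary)
                break
    if any(c is None for c in cells):
        raise DataError("voronoi tessellation failed to match every seed to a region")
    return cells


def generate_demand_units(
    cfg: SynthConfig, area: StudyArea, pop: PopulationRaster
) -> list[DemandUnit]:
    """Tessellate the study area into demand units and aggregate population.

    A raster cell's people belong to the unit containing the cell center,
    so unit populations sum exactly to the raster total.
    """
    n = cfg.demand_unit_count
    if n > pop.counts.size:
        raise DataError(
            f"demand_unit_count={n} exceeds the {pop.counts.size} population raster cells"
        )
    if cfg.tessellation == "grid":
        cells = _grid_tessellation(area, n)
    else:
        cells = _voronoi_tessellation(_rng(cfg, "units"), area, n)

    X, Y = pop.grid.cell_centers()
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    weights = pop.counts.ravel()
    tree = shapely.STRtree(pts)
    populations = np.zeros(len(cells))
    assigned = np.full(len(pts), -1, dtype=int)
    for i, cell in enumerate(cells):
        if cell.is_empty:
            continue
        for j in tree.query(cell, predicate="covers"):
            if assigned[j] < 0:  # boundary centers go to the lowest-index unit
                assigned[j] = i
    # raster centers missed by every polygon (degenerate clipping) -> nearest cell
    for j in np.nonzero((assigned < 0) & (weights > 0))[0]:
        d = shapely.distance(pts[j], np.array(cells, dtype=object))
        assigned[j] = int(np.argmin(d))
    np.add.at(populations, assigned[assigned >= 0], weights[assigned >= 0])
    return [
        DemandUnit(id=f"unit-{i:03d}", geometry=cell, population=float(populations[i]))
        for i, cell in enumerate(cells)
    ]


def generate_city(cfg: SynthConfig) -> dict:
    """Run all generator stages; returns the layer bundle keyed by name."""
    area = generate_study_area(cfg)
    greens = generate_green_spaces(cfg, area)
    pois = generate_pois(cfg, area)
    pop = generate_population(cfg, area, pois)
    units = generate_demand_units(cfg, area, pop)
    return {"area": area, "greens": greens, "pois": pois, "population": pop, "units": units}
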