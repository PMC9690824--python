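"""End-to-end orchestration: synthetic city -> heat -> services -> access -> zoning.

`run_pipeline` is deterministic given the seed: every table it writes is
reproduced byte-identically on a rerun with the same configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__, io
from .access import AccessibilityResult, DecayParams, evaluate_accessibility
from .errors import ConfigError
from .grids import GridSpec
from .heat import HeatSurface, HeatZoneMap, classify_heat, kde_surface, zone_area_table
from .integrate import (
    DEFAULT_MERGE_MAPPING,
    IntegratedZoneMap,
    mapping_from_dicts,
    mapping_to_dicts,
    merge_partitions,
    partition,
    zone_report,
)
from .rounding import ratio_percent, round_half_up
from .service import (
    ServiceLayer,
    build_service_layer,
    composite_service,
    cooling_rule,
    coverage_by_zone,
    disaster_rule,
    overlap_stats,
    recreation_rule,
)
from .synth import SynthConfig, generate_city

log = logging.getLogger("greenserve")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the full run needs; defaults are the study conditions."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    bandwidth_m: float = 1250.0
    heat_grid_m: float = 50.0
    heat_method: str = "jenks"
    kernel: str = "printed"
    access_method: str = "quantile"
    d0_m: float = 1250.0
    mapping_file: str | None = None

    def __post_init__(self) -> None:
        if self.bandwidth_m <= 0 or self.heat_grid_m <= 0 or self.d0_m <= 0:
            raise ConfigError("bandwidth_m, heat_grid_m and d0_m must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("synth", {}).items()
        })
        return cls(synth=synth, **raw)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output plus the report tables."""

    config: PipelineConfig
    city: dict
    surface: HeatSurface
    zones: HeatZoneMap
    zone_areas: pd.DataFrame
    layers: dict[str, ServiceLayer]
    coverage: dict[str, pd.DataFrame]
    composite: shapely.geometry.base.BaseGeometry
    composite_coverage: pd.DataFrame
    access: AccessibilityResult
    zone_map: IntegratedZoneMap
    report: pd.DataFrame
    summary: dict


def _composite_layer(composite, tag: str) -> ServiceLayer:
    return ServiceLayer(
        tag=tag, source_ids=(), buffers=(), union=composite, overlap=shapely.Polygon()
    )


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage in order; optionally write the report bundle to disk."""
    stage = "simulate"
    try:
        city = generate_city(cfg.synth)
        area = city["area"]
        log.info("synthetic city: %.2f km2, %d greens, %d POIs, %d units",
                 area.area_km2, len(city["greens"]), len(city["pois"]), len(city["units"]))

        stage = "heat"
        xmin, ymin, xmax, ymax = area.boundary.bounds
        grid = GridSpec.from_bounds(xmin, ymin, xmax, ymax, cfg.heat_grid_m)
        surface = kde_surface(city["pois"], cfg.bandwidth_m, grid, kernel=cfg.kernel)
        X, Y = grid.cell_centers()
        mask = shapely.contains_xy(area.boundary, X.ravel(), Y.ravel()).reshape(grid.shape)
        zones = classify_heat(surface, method=cfg.heat_method, mask=mask)
        zone_areas = zone_area_table(zones)

        stage = "service"
        rules = [cooling_rule(), recreation_rule(420.0), recreation_rule(1250.0), disaster_rule()]
        layers = {r.tag: build_service_layer(city["greens"], r, area) for r in rules}
        coverage = {tag: coverage_by_zone(layer, zones) for tag, layer in layers.items()}
        composite = composite_service(
            [layers["cooling"], layers["recreation_1250"], layers["disaster"]], area
        )
        composite_coverage = coverage_by_zone(_composite_layer(composite, "composite"), zones)

        stage = "access"
        access = evaluate_accessibility(
            city["greens"], city["units"], DecayParams(d0=cfg.d0_m), method=cfg.access_method
        )

        stage = "integrate"
        mapping = DEFAULT_MERGE_MAPPING
        if cfg.mapping_file:
            mapping = mapping_from_dicts(yaml.safe_load(Path(cfg.mapping_file).read_text()))
        parts = partition(zones, access, city["units"], composite)
        zone_map = merge_partitions(parts, mapping)
        report = zone_report(zone_map)

        stage = "report"
        summary = _summary(cfg, area, layers, composite, access, zones)
        result = PipelineResult(
            config=cfg, city=city, surface=surface, zones=zones, zone_areas=zone_areas,
            layers=layers, coverage=coverage, composite=composite,
            composite_coverage=composite_coverage, access=access, zone_map=zone_map,
            report=report, summary=summary,
        )
        if outdir is not None:
            write_bundle(result, Path(outdir))
        return result
    except Exception as exc:
        from .errors import DataError, GreenserveError

        kind = type(exc) if isinstance(exc, GreenserveError) else DataError
        raise kind(f"pipeline stage {stage!r} failed: {exc}") from exc


def _summary(cfg, area, layers, composite, access, zones) -> dict:
    area_km2 = area.area_km2
    tbl = access.table
    n_units = len(tbl)
    n_above = int(tbl["supply_ge_demand"].sum())
    n_medium_plus = int((tbl["level4"] != "low").sum())
    return {
        "study_area_km2": round_half_up(area_km2, 3),
        "cooling_union_km2": round_half_up(layers["cooling"].union_km2, 3),
        "cooling_coverage_percent": ratio_percent(layers["cooling"].union.area, area.area_m2),
        "cooling_overlap_km2": overlap_stats(layers["cooling"])[0],
        "cooling_overlap_percent_of_union": overlap_stats(layers["cooling"])[1],
        "recreation_420_coverage_percent": ratio_percent(
            layers["recreation_420"].union.area, area.area_m2),
        "recreation_1250_coverage_percent": ratio_percent(
            layers["recreation_1250"].union.area, area.area_m2),
        "recreation_1250_overlap_percent_of_union": overlap_stats(layers["recreation_1250"])[1],
        "disaster_coverage_percent": ratio_percent(layers["disaster"].union.area, area.area_m2),
        "disaster_overlap_percent_of_union": overlap_stats(layers["disaster"])[1],
        "composite_km2": round_half_up(composite.area / 1e6, 3),
        "composite_coverage_percent": ratio_percent(composite.area, area.area_m2),
        "per_capita_benchmark_m2": round_half_up(access.benchmark_m2_per_capita, 3),
        "units_total": n_units,
        "units_supply_ge_demand": n_above,
        "units_medium_or_better_access": n_medium_plus,
        "units_medium_or_better_percent": ratio_percent(n_medium_plus, n_units, 0),
    }


def write_bundle(result: PipelineResult, outdir: Path) -> None:
    """Write vector/raster layers, CSV tables and the JSON run manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    city = result.city
    io.write_study_area(city["area"], outdir / "study_area.geojson")
    io.write_greens(city["greens"], outdir / "greens.geojson")
    io.write_pois(city["pois"], outdir / "pois.geojson")
    io.write_units(city["units"], outdir / "units.geojson")
    io.write_population(city["population"], outdir / "population.asc")
    io.write_raster(result.surface.grid, result.surface.values, outdir / "heat_surface.asc")
    io.write_raster(result.zones.grid, result.zones.labels.astype(float), outdir / "heat_zones.asc")
    io.write_raster(result.zone_map.grid, result.zone_map.labels.astype(float),
                    outdir / "integrated_zones.asc")

    result.zone_areas.to_csv(outdir / "heat_zone_areas.csv", index=False)
    for tag, table in result.coverage.items():
        table.to_csv(outdir / f"coverage_{tag}.csv", index=False)
    result.composite_coverage.to_csv(outdir / "coverage_composite.csv", index=False)
    result.access.table.to_csv(outdir / "accessibility.csv", index=False, float_format="%.9g")
    result.access.ratios.to_csv(outdir / "supply_demand_ratios.csv", index=False,
                                float_format="%.9g")
    result.report.to_csv(outdir / "zone_report.csv", index=False)
    with open(outdir / "mapping.yml", "w") as fh:
        yaml.safe_dump(mapping_to_dicts(DEFAULT_MERGE_MAPPING), fh, sort_keys=True)

    manifest = {
        "package": "greenserve",
        "version": __version__,
        "seed": result.config.synth.seed,
        "d0_m": result.config.d0_m,
        "bandwidth_m": result.config.bandwidth_m,
        "heat_grid_m": result.config.heat_grid_m,
        "heat_method": result.config.heat_method,
        "kernel": result.config.kernel,
        "access_method": result.config.access_method,
        "synth": asdict(result.config.synth),
        "summary": result.summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
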