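"""Readers and writers for the pipeline's layer formats.

Vector layers travel as GeoJSON FeatureCollections carrying a legacy-style
``crs`` member naming the local projected CRS; rasters as ESRI ASCII grid
text with a JSON sidecar for metadata. All coordinates must be projected
planar meters — a geographic (degree) CRS is rejected unless the caller
explicitly overrides, because every distance rule in the method is metric.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .errors import DataError
from .grids import GridSpec
from .types import DemandUnit, GreenSpacePolygon, PoiPoint, PopulationRaster, StudyArea

LOCAL_CRS_NAME = "urn:greenserve:local-meters"
_DEGREE_CRS_NAMES = ("CRS84", "EPSG:4326", "EPSG::4326", "WGS 84", "WGS84")


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _collection(features: list[dict], crs_name: str = LOCAL_CRS_NAME) -> dict:
    return {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_name}},
        "features": features,
    }


def _check_crs(doc: dict, path: Path, assume_projected: bool) -> None:
    crs = doc.get("crs")
    if crs is None:
        if assume_projected:
            return
        raise DataError(
            f"{path}: no CRS declared; GeoJSON defaults to geographic degrees "
            "(OGC:CRS84) — pass assume_projected=True if coordinates are planar meters"
        )
    name = str(crs.get("properties", {}).get("name", ""))
    if any(tag.lower() in name.lower() for tag in _DEGREE_CRS_NAMES) and not assume_projected:
        raise DataError(
            f"{path}: geographic (degree) CRS {name!r} is not supported; "
            "reproject to planar meters or pass assume_projected=True"
        )


def _load_collection(path: str | Path, assume_projected: bool) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.suffix.lower() not in (".geojson", ".json"):
        raise DataError(f"{path}: unknown vector format {path.suffix!r} (expected .geojson)")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"{path}: not valid JSON ({exc})") from None
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: expected a GeoJSON FeatureCollection")
    _check_crs(doc, path, assume_projected)
    return doc


def write_study_area(area: StudyArea, path: str | Path) -> None:
    doc = _collection([_feature(area.boundary, {"kind": "study_area"})])
    Path(path).write_text(json.dumps(doc))


def read_study_area(path: str | Path, assume_projected: bool = False) -> StudyArea:
    doc = _load_collection(path, assume_projected)
    if not doc["features"]:
        raise DataError(f"{path}: empty study-area layer")
    return StudyArea(boundary=shape(doc["features"][0]["geometry"]))


def write_greens(greens: list[GreenSpacePolygon], path: str | Path) -> None:
    feats = [
        _feature(g.geometry, {"id": g.id, "category": g.category, "area_m2": g.area_m2})
        for g in greens
    ]
    Path(path).write_text(json.dumps(_collection(feats)))


def read_greens(path: str | Path, assume_projected: bool = False) -> list[GreenSpacePolygon]:
    doc = _load_collection(path, assume_projected)
    out = []
    for f in doc["features"]:
        props = f.get("properties", {})
        out.append(
            GreenSpacePolygon(
                id=str(props["id"]), geometry=shape(f["geometry"]), category=props["category"]
            )
        )
    return out


def write_pois(pois: list[PoiPoint], path: str | Path) -> None:
    from shapely.geometry import Point

    feats = [
        _feature(Point(p.x, p.y), {"id": p.id, "category": p.category}) for p in pois
    ]
    Path(path).write_text(json.dumps(_collection(feats)))


def read_pois(path: str | Path, assume_projected: bool = False) -> list[PoiPoint]:
    doc = _load_collection(path, assume_projected)
    out = []
    for f in doc["features"]:
        x, y = f["geometry"]["coordinates"][:2]
        props = f.get("properties", {})
        out.append(PoiPoint(id=str(props["id"]), x=x, y=y, category=str(props["category"])))
    return out


def write_units(units: list[DemandUnit], path: str | Path) -> None:
    feats = [
        _feature(u.geometry, {"id": u.id, "population": u.population}) for u in units
    ]
    Path(path).write_text(json.dumps(_collection(feats)))


def read_units(path: str | Path, assume_projected: bool = False) -> list[DemandUnit]:
    doc = _load_collection(path, assume_projected)
    return [
        DemandUnit(
            id=str(f["properties"]["id"]),
            geometry=shape(f["geometry"]),
            population=float(f["properties"]["population"]),
        )
        for f in doc["features"]
    ]


def write_raster(grid: GridSpec, values: np.ndarray, path: str | Path) -> None:
    """ESRI ASCII grid (row 0 north), full float precision."""
    path = Path(path)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xmin!r}\n"
        f"yllcorner {grid.ymin!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value -9999\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in values)
    path.write_text(header + body + "\n")


def read_raster(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    try:
        meta = {}
        for line in lines[:6]:
            key, val = line.split()
            meta[key.lower()] = val
        grid = GridSpec(
            xmin=float(meta["xllcorner"]),
            ymin=float(meta["yllcorner"]),
            cell_size=float(meta["cellsize"]),
            nrows=int(meta["nrows"]),
            ncols=int(meta["ncols"]),
        )
        values = np.array([[float(v) for v in line.split()] for line in lines[6:] if line])
    except (ValueError, KeyError) as exc:
        raise DataError(f"{path}: malformed ASCII grid ({exc})") from None
    if values.shape != grid.shape:
        raise DataError(f"{path}: grid body shape {values.shape} != header {grid.shape}")
    return grid, values


def write_population(pop: PopulationRaster, path: str | Path) -> None:
    write_raster(pop.grid, pop.counts, path)


def read_population(path: str | Path) -> PopulationRaster:
    grid, values = read_raster(path)
    return PopulationRaster(grid=grid, counts=values)
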