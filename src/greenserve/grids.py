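"""Regular raster grids in projected planar meters.

A :class:`GridSpec` describes cell geometry only; values live in plain numpy
arrays shaped ``(nrows, ncols)`` with row 0 the northernmost row (the ESRI
ASCII grid convention, so arrays print the way the map looks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: lower-left origin, square cells."""

    xmin: float
    ymin: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size must be positive, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ConfigError("grid must have at least one row and one column")

    @classmethod
    def from_bounds(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, cell_size: float
    ) -> "GridSpec":
        """Smallest grid of ``cell_size`` cells covering the bounding box."""
        if xmax <= xmin or ymax <= ymin:
            raise ConfigError("empty bounding box")
        ncols = int(np.ceil((xmax - xmin) / cell_size))
        nrows = int(np.ceil((ymax - ymin) / cell_size))
        return cls(xmin=xmin, ymin=ymin, cell_size=cell_size, nrows=nrows, ncols=ncols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinates, each shaped (nrows, ncols), row 0 north."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (clipped to grid)."""
        col = np.clip(((np.asarray(x) - self.xmin) // self.cell_size).astype(int), 0, self.ncols - 1)
        row = np.clip(((self.ymax - np.asarray(y)) // self.cell_size).astype(int), 0, self.nrows - 1)
        return row, col
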