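import numpy as np
import pytest
from shapely.geometry import box

import greenserve as gs


@pytest.fixture(scope="session")
def small_cfg() -> gs.SynthConfig:
    """A compact city small enough for geometric oracles to be cheap."""
    return gs.SynthConfig(
        seed=7,
        extent_m=(3000.0, 3000.0),
        n_parks=12,
        n_buffers=3,
        n_poi=200,
        population_total=20_000,
        demand_unit_count=25,
    )


@pytest.fixture(scope="session")
def small_city(small_cfg) -> dict:
    return gs.generate_city(small_cfg)


@pytest.fixture(scope="session")
def unit_square_area() -> gs.StudyArea:
    return gs.StudyArea(boundary=box(0.0, 0.0, 1000.0, 1000.0))


def raster_count_area(geom, bounds, cell=5.0) -> float:
    """Independent area oracle: count cell centers of a fine grid inside geom."""
    import shapely

    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin + cell / 2, xmax, cell)
    ys = np.arange(ymin + cell / 2, ymax, cell)
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, X.ravel(), Y.ravel())
    return float(inside.sum()) * cell * cell


def brute_force_kde(pois, h, grid, kernel="printed"):
    """Double loop over (cell, POI): the independent KDE oracle."""
    X, Y = grid.cell_centers()
    out = np.zeros(grid.shape)
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            s = 0.0
            for p in pois:
                d2 = (X[r, c] - p.x) ** 2 + (Y[r, c] - p.y) ** 2
                u2 = d2 / (h * h)
                if u2 <= 1.0:
                    if kernel == "printed":
                        s += (1.0 - u2) / (np.pi * h * h)
                    else:
                        s += 3.0 / (np.pi * h * h) * (1.0 - u2) ** 2
            out[r, c] = s
    return out


def brute_force_2sfca(units, parks, d0):
    """Independent two-loop implementation of the two catchment steps."""
    import math

    e_half = math.exp(-0.5)

    def G(d):
        if d > d0:
            return 0.0
        return (math.exp(-0.5 * (d / d0) ** 2) - e_half) / (1.0 - e_half)

    def dist(u, g):
        uc, pc = u.centroid, g.centroid
        return math.hypot(uc.x - pc.x, uc.y - pc.y)

    R = {}
    for g in parks:
        denom = sum(G(dist(u, g)) * u.population for u in units if dist(u, g) <= d0)
        if denom > 0:
            R[g.id] = g.area_m2 / denom
    A = []
    for u in units:
        A.append(
            sum(G(dist(u, g)) * R[g.id] for g in parks if g.id in R and dist(u, g) <= d0)
        )
    return R, np.array(A)
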