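# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `greenserve`, and what the synthetic-data tests do and
do not demonstrate about real cities.

## Life-heat surface

POI kernel density uses the finite-support parabolic profile
`(1/πh²)(1 − d²/h²)` on `d ≤ h`. Two properties matter:

* **Mass.** The profile integrates to exactly ½ over its support disk
  (verified by quadrature in `kernel_mass`). It is therefore a relative
  intensity surface, not a probability density; since the zoning step only
  ranks cells, the constant factor is irrelevant downstream. Users who
  want unit mass can pass `kernel="quartic"`, the standard quartic
  (biweight) kernel `(3/πh²)(1 − d²/h²)²`.
* **Bandwidth.** h defaults to 1250 m — the 15-minute walking circle, the
  only distance scale the method otherwise endorses. It is configurable;
  zone boundaries move with it, the pipeline mechanics do not.

The surface is evaluated at 50 m cell centers by default (configurable).
Classification into five ordered zones defaults to Fisher–Jenks natural
breaks, computed by exact dynamic programming on the sorted cell values;
inputs beyond 2500 values are thinned to 2500 evenly spaced order
statistics first, which perturbs breaks negligibly for smooth surfaces
while keeping the DP O(k·n²) cost bounded. Quantile and equal-interval
methods are provided. Ties sit with the colder class (a value equal to a
break belongs below it), making labels a monotone function of value.

## Service radii

* **Cooling** uses the logarithmic area–radius fit y = 53.668 ln x −
  448.33 with x in m² and y in meters. These units give a zero-crossing at
  exp(448.33/53.668) ≈ 4246 m² and ≈293 m at 1 km², consistent with the
  urban cooling-distance literature; the raw value is clamped at 0, so
  sub-threshold patches serve only their own footprint.
* **Recreation** serves park-category patches only. The two scales are
  cumulative disks, not annuli: the 1250 m layer is the full 0–1250 m
  buffer (its coverage must exceed the 420 m layer's). 420 m is kept as
  the conventional printed value for the <5-minute walk (416.7 m exactly
  at 5 km/h).
* **Disaster shelter** is piecewise-constant in patch size. Parks under
  the smallest tabulated class (0.5 ha) provide no shelter service;
  protective strips need ≥0.5 ha for their 300 m radius.

Buffers are measured outward from polygon boundaries, never centroids, and
the source footprint always counts as served. "Overlap" is the region
covered by at least two *individual* buffers before dissolving, clipped to
the study area — the only definition under which overlap is a subset of
the union. The composite three-service space is the geometric intersection
of the cooling, 1250 m recreation and disaster unions. All areas are exact
shapely polygon areas; an independent 5 m raster-counting oracle agrees
within 0.5% in the tests.

## Accessibility (G2SFCA)

Distances are Euclidean between demand-unit centroids and park geometric
centroids. A network (road) metric would be preferable where road data
exist; the distance backend is one function (`euclidean_distances`) so it
can be swapped without touching either catchment step. Both steps use the
same distance matrix and the same truncated-Gaussian weights, which is
what makes the conservation identity Σ D_i·A_i = Σ served S_j exact
(tested to 1e-9 relative over 100 random instances; observed residuals are
at machine precision).

Parks whose catchment contains no weighted demand get no supply–demand
ratio: they are flagged unserved and contribute nothing to any A_i
(treating them as infinite-supply would be the other choice; unserved is
the conservative one and keeps conservation meaningful). The supply flag
per unit is A_i ≥ citywide park area per capita; the threshold is a plain
number and can be replaced.

Accessibility classes default to quantiles (k = 4: low, medium, mid-high,
high; Jenks optional). The 3-level collapse used by the overlay maps
mid-high and high to "high". Degenerate surfaces (all-equal A, e.g. a
parkless city) cannot be classified and are reported uniformly "low"; the
classifier itself raises on such input.

## Integrated zoning

Heat levels collapse 5→3 as {Cold, Sub-Cold}→low, {Not-Significant}→
medium, {Sub-Hot, Hot}→high. The merge from 18 partition codes to six
named areas keys on (supply flag, heat group low vs. medium/high, service
flag). Six of the eight key combinations follow the published six-row
table; the two it omits are resolved to the row differing in exactly one
field — (supply≥demand, low heat, not-enjoy) → Green space service blind
area, (supply<demand, low heat, enjoy) → Livable area — and the whole
mapping ships as YAML so either default can be overridden. Under the
default mapping, granting a cell service never moves it into a "blind"
zone (a tested monotonicity property).

## Synthetic city

The generator emulates the statistical structure the analysis assumes,
at the study's stated conditions: a ~45.5 km² rectangular built-up area
(7000 × 6500 m; a seeded irregular outline is optional), 1294 POIs, a
100 m population raster, and 233 demand units. Values neither stated nor
derivable were fixed once at field-plausible levels: 30 parks and 8
protective strips (enough to populate all four disaster size classes and
the river-following strip geometry), 160,000 residents (the order of a
small border city's built-up population), and a POI mixture of three
Gaussian clusters — the heaviest (weight 0.55, spread 500 m) on the
"old-town" core at ~(0.36 W, 0.42 H) — over a 15% uniform background.
Park areas are log-uniform over 5·10³–10⁶ m², stratified so every size
class the range permits is populated. Population is blurred POI intensity
(300 m Gaussian) plus a 20% uniform floor, normalized exactly to the
total. Demand units default to an exact-count near-square grid (equal
rows, per-row column counts differing by one — handles the prime 233);
seeded Voronoi is optional. Every stage has its own seeded RNG stream, so
one config is bit-reproducible through to serialized bytes.

What the synthetic city does **not** emulate: street networks (hence no
network distances), correlated park/POI placement, irregular real park
shapes, temporally varying activity, or census-style heterogeneity in
demand. Green tests on this city show the pipeline's arithmetic and
invariants are right; they do not validate the cooling regression, the
radii table or the decay model against any real landscape.

## Numerical conventions

* Percentages round half-up at 2 decimals, areas at 3; rounding happens
  only in report tables, never inside computations.
* Heat/overlay rasters use 50 m cells; zone polygons are exact unions of
  cell squares, so coverage ratios are exact areas of polygon
  intersections, not cell counts.
* Default problem sizes (50 m heat grid over 45.5 km², ≤38 green sources,
  233 units) run the full pipeline in a few seconds on one CPU; the test
  oracles use smaller instances (≤50 points, ≤20 polygons, 5 m counting
  grids) chosen so brute force stays cheap.
* One published internal ratio (35.60/48.34 printed as 73.64%) is not
  reproducible under any single rounding convention — the quotient is
  73.645…% — and the corresponding regression case documents this rather
  than special-casing it.

## Limitations

Euclidean distance overstates access wherever the street grid detours;
the per-capita benchmark is a citywide scalar, blind to subgroup equity;
POI density proxies activity but weights all 19 categories equally; and
the five-zone heat classification depends on the (unstatable) bandwidth
and break method, so cross-city comparisons should fix both.
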