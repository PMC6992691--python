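"""Range statistics used to screen for likely Least Concern status.

Four statistics are computed from the native-filtered occurrence points:

EOO
    Extent of occurrence — the area (km²) of the minimum convex polygon
    of all points. Fewer than three distinct points, or collinear points,
    give EOO 0 with a warning (a degenerate hull has no area).
AOO
    Area of occupancy — the number of occupied grid cells times the cell
    area, on a coarse 10 km × 10 km grid by default (one occupied cell =
    100 km²). The coarse cell absorbs typical georeference error; this is
    a screening statistic, deliberately not the 2 km × 2 km
    assessment-grade estimate.
RecordCount
    Number of unique georeferenced records within the native range.
TDWGCount
    Number of native Level-3 regions actually occupied by ≥1 point.

Areas are measured after projecting each species' points with its own
equal-area cylindrical projection (see :mod:`lcscreen.projection`). The
occupancy grid is anchored at the south-west corner of the projected
point cloud, which makes the cell count deterministic, invariant to
translation of the whole cloud, and guarantees a cluster tighter than
one cell width occupies exactly one cell; no search over grid offsets
is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .errors import ConfigurationError
from .projection import ProjectionContext
from .regions import FilteredOccurrences

#: Default occupancy-grid cell edge, km.
DEFAULT_CELL_KM = 10.0

WARN_NO_POINTS = (
    "no georeferenced points within the native range to carry out the area calculations"
)
WARN_DEGENERATE_EOO = "fewer than three non-collinear points; EOO set to 0"


@dataclass(frozen=True)
class RangeMetrics:
    """The four screening statistics for one taxon."""

    eoo_km2: float
    aoo_km2: float
    record_count: int
    tdwg_count: int
    warning: str = ""


def _unique_projected(points: FilteredOccurrences, ctx: ProjectionContext) -> np.ndarray:
    """Unique retained coordinate pairs, projected to km; shape (n, 2)."""
    coords = list(dict.fromkeys(points.retained.coordinates()))
    if not coords:
        return np.empty((0, 2))
    arr = np.asarray(coords, dtype=float)
    x, y = ctx.forward(arr[:, 0], arr[:, 1])
    return np.column_stack([x, y])


def make_projection(points: FilteredOccurrences) -> ProjectionContext:
    """Equal-area projection centred on the retained points' means."""
    coords = points.retained.coordinates()
    lons = [c[0] for c in coords]
    lats = [c[1] for c in coords]
    return ProjectionContext.from_points(lons, lats)


def compute_eoo(points: FilteredOccurrences, ctx: ProjectionContext) -> float:
    """Convex-hull (minimum convex polygon) area in km².

    Degenerate inputs — fewer than three distinct points, or all points
    collinear — return 0; the composite metrics carry the warning.
    """
    xy = _unique_projected(points, ctx)
    if xy.shape[0] < 3:
        return 0.0
    hull = MultiPoint(xy).convex_hull
    # collinear point sets collapse to a LineString with zero area
    return float(hull.area) if hull.geom_type == "Polygon" else 0.0


def occupied_cells(
    points: FilteredOccurrences, ctx: ProjectionContext, cell_km: float = DEFAULT_CELL_KM
) -> set[tuple[int, int]]:
    """Distinct occupancy-grid cell indices covering the points.

    The grid is anchored at the projected point cloud's (min x, min y)
    corner; each point maps to ``(floor((x-x0)/cell), floor((y-y0)/cell))``.
    """
    if cell_km <= 0:
        raise ConfigurationError(f"cell size must be positive, got {cell_km}")
    xy = _unique_projected(points, ctx)
    if xy.shape[0] == 0:
        return set()
    anchored = xy - xy.min(axis=0)
    idx = np.floor(anchored / cell_km).astype(int)
    return {(int(i), int(j)) for i, j in idx}


def compute_aoo(
    points: FilteredOccurrences, ctx: ProjectionContext, cell_km: float = DEFAULT_CELL_KM
) -> float:
    """Grid area of occupancy in km²: occupied cell count × cell area."""
    return len(occupied_cells(points, ctx, cell_km)) * cell_km**2


def count_records(points: FilteredOccurrences) -> int:
    """Number of unique retained coordinate pairs."""
    return len(set(points.retained.coordinates()))


def count_tdwg(points: FilteredOccurrences) -> int:
    """Number of native Level-3 regions with at least one retained point."""
    return len(points.regions_hit)


def compute_metrics(
    points: FilteredOccurrences,
    ctx: ProjectionContext | None = None,
    cell_km: float = DEFAULT_CELL_KM,
) -> RangeMetrics:
    """All four statistics, with warnings for degenerate inputs."""
    if ctx is None:
        ctx = make_projection(points)
    n = count_records(points)
    if n == 0:
        return RangeMetrics(0.0, 0.0, 0, 0, warning=WARN_NO_POINTS)
    eoo = compute_eoo(points, ctx)
    warning = WARN_DEGENERATE_EOO if eoo == 0.0 else ""
    return RangeMetrics(
        eoo_km2=eoo,
        aoo_km2=compute_aoo(points, ctx, cell_km),
        record_count=n,
        tdwg_count=count_tdwg(points),
        warning=warning,
    )
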