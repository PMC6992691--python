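"""Shared fixtures and independent geometry/counting oracles.

The oracles here deliberately re-derive results from first principles
(pairwise hull-edge enumeration, even-odd ray casting, per-record
counting loops) so the implementation under test is checked against code
that shares none of its geometry or vectorisation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from lcscreen.occurrences import OccurrenceRecord, OccurrenceSet
from lcscreen.regions import FilteredOccurrences
from lcscreen.synth import gen_fixture_suite
from lcscreen.workflow import load_fixture_backends


@pytest.fixture(scope="session")
def demo_world(tmp_path_factory):
    """A generated offline fixture world shared by the integration tests."""
    d = tmp_path_factory.mktemp("demo_world")
    paths = gen_fixture_suite(d, seed=0)
    return d, paths


@pytest.fixture(scope="session")
def demo_backends(demo_world):
    d, _ = demo_world
    return load_fixture_backends(d)


def occ_set(coords, taxon_ref="t", limit=None):
    """Build an OccurrenceSet straight from (lon, lat) pairs."""
    records = tuple(
        OccurrenceRecord(longitude=float(lo), latitude=float(la), source_id=f"r{i}")
        for i, (lo, la) in enumerate(coords)
    )
    return OccurrenceSet(
        taxon_ref=taxon_ref,
        records=records,
        requested_limit=limit if limit is not None else max(1, len(records)),
    )


def filtered(coords, regions_hit=frozenset(), removed=0):
    """Build FilteredOccurrences directly, bypassing the spatial filter."""
    return FilteredOccurrences(
        retained=occ_set(coords), removed_count=removed,
        regions_hit=frozenset(regions_hit),
    )


# ---------------------------------------------------------------------------
# Oracles


def hull_area_bruteforce(points: np.ndarray) -> float:
    """Convex-hull area by O(n^3) hull-edge enumeration plus shoelace.

    A directed pair (i, j) is a hull edge iff every other point lies on
    one side of the line through it; hull vertices are then ordered by
    angle around their centroid and the polygon area taken with the
    shoelace formula.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    d = pts[None, :, :] - pts[:, None, :]  # d[i, j] = pj - pi, shape (n, n, 2)
    # cross[i, j, k] = cross(pj - pi, pk - pi)
    cross = (
        d[:, :, None, 0] * d[:, None, :, 1] - d[:, :, None, 1] * d[:, None, :, 0]
    )
    scale = np.abs(pts).max() ** 2 + 1.0
    tol = 1e-12 * scale
    is_edge = np.all(cross >= -tol, axis=2) | np.all(cross <= tol, axis=2)
    np.fill_diagonal(is_edge, False)
    on_hull = np.where(is_edge.any(axis=1))[0]
    hull = pts[on_hull]
    if len(hull) < 3:
        return 0.0
    centroid = hull.mean(axis=0)
    order = np.argsort(np.arctan2(hull[:, 1] - centroid[1], hull[:, 0] - centroid[0]))
    hull = hull[order]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _on_segment(p, a, b, tol=1e-12) -> bool:
    cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    if abs(cross) > tol * (abs(b[0] - a[0]) + abs(b[1] - a[1]) + 1.0):
        return False
    return (
        min(a[0], b[0]) - tol <= p[0] <= max(a[0], b[0]) + tol
        and min(a[1], b[1]) - tol <= p[1] <= max(a[1], b[1]) + tol
    )


def point_in_ring_raycast(point, ring) -> bool:
    """Even-odd ray-casting test on one closed ring; boundary counts inside."""
    x, y = point
    n = len(ring)
    inside = False
    for i in range(n):
        a = ring[i]
        b = ring[(i + 1) % n]
        if _on_segment((x, y), a, b):
            return True
        (x1, y1), (x2, y2) = a, b
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def count_cells_bruteforce(xy: np.ndarray, cell: float) -> int:
    """Occupied-cell count by per-point enumeration on the min-anchored grid."""
    xy = np.unique(np.asarray(xy, dtype=float), axis=0)
    if len(xy) == 0:
        return 0
    x0 = xy[:, 0].min()
    y0 = xy[:, 1].min()
    cells = set()
    for x, y in xy:
        cells.add((math.floor((x - x0) / cell), math.floor((y - y0) / cell)))
    return len(cells)


def confusion_naive(values, truths, threshold):
    """Per-record confusion tally with an explicit loop."""
    tp = fp = tn = fn = 0
    for v, truth in zip(values, truths):
        pred = v >= threshold
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
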