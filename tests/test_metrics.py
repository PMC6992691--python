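"""Range statistics: EOO hull area, grid AOO, record and region counts."""

import numpy as np
import pytest

from conftest import count_cells_bruteforce, filtered, hull_area_bruteforce
from lcscreen.metrics import (
    WARN_DEGENERATE_EOO,
    WARN_NO_POINTS,
    compute_aoo,
    compute_eoo,
    compute_metrics,
    count_records,
    count_tdwg,
    make_projection,
    occupied_cells,
)
from lcscreen.projection import ProjectionContext


def from_projected(xy, ctx):
    """Lon/lat preimages of projected km coordinates under ctx."""
    xy = np.asarray(xy, dtype=float)
    lon, lat = ctx.inverse(xy[:, 0], xy[:, 1])
    return filtered(list(zip(lon, lat)))


def test_projection_round_trip():
    ctx = ProjectionContext(24.0, -15.0)
    lons = np.array([20.0, 24.0, 30.0, -170.0])
    lats = np.array([-10.0, -15.0, 5.0, 60.0])
    lon2, lat2 = ctx.inverse(*ctx.forward(lons, lats))
    np.testing.assert_allclose(lon2, lons, atol=1e-9)
    np.testing.assert_allclose(lat2, lats, atol=1e-9)


def test_eoo_of_a_100km_square_is_10000_km2():
    ctx = ProjectionContext(12.0, -20.0)
    square = [(0.0, 0.0), (100.0, 0.0), (100.0, 100.0), (0.0, 100.0)]
    pts = from_projected(square, ctx)
    assert compute_eoo(pts, ctx) == pytest.approx(10000.0, rel=1e-9)


@pytest.mark.parametrize(
    "coords",
    [[], [(1.0, 2.0)], [(1.0, 2.0), (3.0, 4.0)]],
)
def test_eoo_degenerate_point_counts_give_zero(coords):
    pts = filtered(coords)
    assert compute_eoo(pts, ProjectionContext(0.0, 0.0)) == 0.0


def test_eoo_collinear_points_give_zero_with_warning():
    ctx = ProjectionContext(0.0, 0.0)
    pts = from_projected([(0.0, 0.0), (50.0, 50.0), (100.0, 100.0)], ctx)
    assert compute_eoo(pts, ctx) == 0.0
    m = compute_metrics(pts)
    assert m.eoo_km2 == 0.0 and m.warning == WARN_DEGENERATE_EOO


def test_hull_area_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    ctx = ProjectionContext(10.0, 10.0)
    for _ in range(50):
        n = int(rng.integers(3, 101))
        xy = rng.uniform(-500, 500, (n, 2))
        pts = from_projected(xy, ctx)
        lonlat = np.asarray(pts.retained.coordinates())
        x, y = ctx.forward(lonlat[:, 0], lonlat[:, 1])
        expected = hull_area_bruteforce(np.column_stack([x, y]))
        assert compute_eoo(pts, ctx) == pytest.approx(expected, rel=1e-6)


def test_adding_a_point_never_decreases_eoo():
    rng = np.random.default_rng(5)
    ctx = ProjectionContext(0.0, 0.0)
    base = rng.uniform(-300, 300, (12, 2)).tolist()
    area = compute_eoo(from_projected(base, ctx), ctx)
    for _ in range(20):
        extra = rng.uniform(-600, 600, 2).tolist()
        assert compute_eoo(from_projected(base + [extra], ctx), ctx) >= area - 1e-9


def test_aoo_single_occupied_cell_is_cell_area():
    ctx = ProjectionContext(30.0, -25.0)
    cluster = [(0.3, 0.4), (1.1, 0.2), (0.0, 0.0), (2.0, 3.0), (0.5, 2.5)]
    pts = from_projected(cluster, ctx)
    assert compute_aoo(pts, ctx) == 100.0
    assert compute_aoo(pts, ctx, cell_km=2.0) > 4.0  # finer grid splits it


def test_aoo_zero_points_and_warning():
    pts = filtered([])
    assert compute_aoo(pts, ProjectionContext(0.0, 0.0)) == 0.0
    m = compute_metrics(pts)
    assert m == type(m)(0.0, 0.0, 0, 0, warning=WARN_NO_POINTS)


def test_aoo_matches_bruteforce_cell_enumeration():
    rng = np.random.default_rng(9)
    ctx = ProjectionContext(0.0, 0.0)
    for _ in range(50):
        n = int(rng.integers(1, 101))
        xy = rng.uniform(-400, 400, (n, 2))
        pts = from_projected(xy, ctx)
        lonlat = np.asarray(pts.retained.coordinates())
        x, y = ctx.forward(lonlat[:, 0], lonlat[:, 1])
        expected = count_cells_bruteforce(np.column_stack([x, y]), 10.0)
        assert compute_aoo(pts, ctx) == expected * 100.0


def test_aoo_bounds_and_scale_law():
    rng = np.random.default_rng(13)
    ctx = ProjectionContext(0.0, 0.0)
    for _ in range(25):
        xy = rng.uniform(-300, 300, (int(rng.integers(1, 60)), 2))
        pts = from_projected(xy, ctx)
        n = count_records(pts)
        cells10 = len(occupied_cells(pts, ctx, 10.0))
        cells5 = len(occupied_cells(pts, ctx, 5.0))
        assert 1 <= cells10 <= n
        assert cells10 <= cells5 <= 4 * cells10


def test_aoo_stable_under_within_cell_jitter():
    rng = np.random.default_rng(17)
    ctx = ProjectionContext(0.0, 0.0)
    base = np.array([[0.0, 0.0], [25.0, 3.0], [41.0, 77.0], [13.0, 55.0], [95.0, 95.0]])
    pts = from_projected(base, ctx)
    cells = occupied_cells(pts, ctx, 10.0)
    # jitter every point within its own cell; the anchor point (0, 0) of the
    # min-anchored grid stays put so cell boundaries do not move
    for _ in range(20):
        jittered = base.copy().astype(float)
        for i in range(1, len(base)):
            x0, y0 = np.floor(base[i] / 10.0) * 10.0
            jittered[i] = [
                rng.uniform(x0 + 1e-6, x0 + 10 - 1e-6),
                rng.uniform(y0 + 1e-6, y0 + 10 - 1e-6),
            ]
        assert occupied_cells(from_projected(jittered, ctx), ctx, 10.0) == cells


def test_count_records_is_unique_pair_cardinality():
    assert count_records(filtered([])) == 0
    assert count_records(filtered([(1.0, 2.0)])) == 1
    coords = [(0.0, 1.0), (2.0, 3.0), (0.0, 1.0), (4.0, 5.0), (2.0, 3.0),
              (6.0, 7.0), (8.0, 9.0), (4.0, 5.0), (10.0, 11.0), (12.0, 13.0)]
    assert count_records(filtered(coords)) == 7


def test_count_tdwg_is_occupied_region_count():
    assert count_tdwg(filtered([(1.0, 1.0)], regions_hit={"BER"})) == 1
    assert count_tdwg(filtered([], regions_hit=set())) == 0
    assert count_tdwg(filtered([(1.0, 1.0)], regions_hit={"AAA", "BBB", "CCC"})) == 3


def test_metrics_are_permutation_invariant():
    rng = np.random.default_rng(21)
    coords = [tuple(c) for c in rng.uniform(0, 5, (15, 2))]
    m1 = compute_metrics(filtered(coords, regions_hit={"AAA"}))
    perm = [coords[i] for i in rng.permutation(len(coords))]
    m2 = compute_metrics(filtered(perm, regions_hit={"AAA"}))
    assert m1 == m2


def test_composite_metrics_consistent_for_a_tight_cluster():
    ctx = ProjectionContext(20.0, -10.0)
    cluster = [(0.1, 0.2), (0.4, 0.1), (0.2, 0.5), (0.3, 0.3)]
    pts = from_projected(cluster, ctx)
    m = compute_metrics(pts)
    assert m.aoo_km2 == 100.0
    assert 0 < m.eoo_km2 < 1.0
    assert m.record_count == 4
    assert m.warning == ""


def test_projection_context_recomputed_from_points():
    ctx = make_projection(filtered([(10.0, 20.0), (30.0, 40.0)]))
    assert ctx.central_meridian == pytest.approx(20.0)
    assert ctx.standard_parallel == pytest.approx(30.0)
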