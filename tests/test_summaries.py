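import math

import numpy as np
import pytest

from conftest import make_diagram, random_diagram
from fundustda.summaries import (
    DegenerateCloudError,
    EmptyDiagramError,
    apf,
    apf_area,
    average_lifetime,
    convex_peel,
    count_points,
    landscape,
    landscape_polygon,
    peel_polygon,
    polygon_summary,
)
from shapely.geometry import Polygon


def tents_on_grid(diagram, ts, k):
    """Independent k-th landscape oracle: k-th largest tent on a dense grid."""
    b, d = diagram.births[:, None], diagram.deaths[:, None]
    tents = np.maximum(0.0, np.minimum(ts[None, :] - b, d - ts[None, :]))
    if len(diagram) < k:
        return np.zeros_like(ts)
    return np.sort(tents, axis=0)[-k, :]


class TestScalarSummaries:
    def test_count_points(self):
        assert count_points(make_diagram(np.empty((0, 2)))) == 0
        assert count_points(make_diagram([(0, 1), (0, 3), (2, 5)])) == 3

    def test_average_lifetime(self):
        assert average_lifetime(make_diagram([(0, 1), (0, 3)])) == pytest.approx(2.0)
        assert average_lifetime(make_diagram([(1, 2)])) == pytest.approx(1.0)
        assert average_lifetime(make_diagram([(1, 1), (4, 4)])) == 0.0

    def test_average_lifetime_empty_diagram_rejected(self):
        with pytest.raises(EmptyDiagramError):
            average_lifetime(make_diagram(np.empty((0, 2))))

    def test_apf_is_monotone_with_total_lifetime_terminal_value(self):
        dgm = random_diagram(np.random.default_rng(0), 40)
        mids, steps = apf(dgm)
        assert np.all(np.diff(mids) >= 0)
        assert np.all(np.diff(steps) >= 0)
        assert steps[-1] == pytest.approx(dgm.lifetimes.sum())

    @pytest.mark.parametrize(
        "pairs, rng_interval, expected",
        [([(0, 2)], (0, 2), 2.0), ([(0, 2), (1, 3)], (0, 3), 6.0)],
    )
    def test_apf_area_closed_forms(self, pairs, rng_interval, expected):
        assert apf_area(make_diagram(pairs), rng_interval) == pytest.approx(expected)

    def test_apf_area_matches_dense_riemann_sum(self):
        rng = np.random.default_rng(1)
        dgm = random_diagram(rng, 50, scale=1.0)
        lo, hi = dgm.births.min() - 0.5, dgm.deaths.max() + 0.5
        # midpoint Riemann sum of the step function on a 10^6-cell grid
        edges = np.linspace(lo, hi, 1_000_001)
        mids_grid = (edges[:-1] + edges[1:]) / 2
        jump_locs, steps = apf(dgm)
        idx = np.searchsorted(jump_locs, mids_grid, side="right")
        values = np.concatenate([[0.0], steps])[idx]
        riemann = values.sum() * (hi - lo) / 1_000_000
        assert apf_area(dgm, (lo, hi)) == pytest.approx(riemann, abs=1e-4)


class TestLandscape:
    def test_single_pair_is_one_tent(self):
        fn = landscape(make_diagram([(0, 2)]), 1)
        np.testing.assert_allclose(fn.breakpoints, [(0, 0), (1, 1), (2, 0)])

    def test_k_beyond_point_count_is_zero(self):
        assert landscape(make_diagram([(0, 2)]), 2).is_zero

    def test_duplicate_pairs_give_equal_levels(self):
        dgm = make_diagram([(0, 2), (0, 2)])
        np.testing.assert_array_equal(
            landscape(dgm, 1).breakpoints, landscape(dgm, 2).breakpoints
        )

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_dense_grid_oracle(self, k):
        rng = np.random.default_rng(2)
        for _ in range(10):
            dgm = random_diagram(rng, rng.integers(1, 30))
            ts = np.linspace(dgm.births.min() - 1, dgm.deaths.max() + 1, 2001)
            np.testing.assert_allclose(
                landscape(dgm, k)(ts), tents_on_grid(dgm, ts, k), atol=1e-12
            )

    def test_majorization_over_random_diagrams(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            dgm = random_diagram(rng, rng.integers(3, 25))
            ts = np.linspace(dgm.births.min(), dgm.deaths.max(), 500)
            l1, l2, l3 = (landscape(dgm, k)(ts) for k in (1, 2, 3))
            assert np.all(l1 >= l2 - 1e-12) and np.all(l2 >= l3 - 1e-12)

    def test_one_lipschitz(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            dgm = random_diagram(rng, rng.integers(1, 20))
            for k in (1, 2, 3):
                bp = landscape(dgm, k).breakpoints
                if len(bp) < 2:
                    continue
                slopes = np.diff(bp[:, 1]) / np.diff(bp[:, 0])
                assert np.all(np.abs(slopes) <= 1 + 1e-12)


class TestLandscapePolygon:
    def test_single_tent_triangle_closed_form(self):
        ps = landscape_polygon(make_diagram([(0, 2)]), 1)
        p = 2 + 2 * math.sqrt(2)
        assert ps.area == pytest.approx(1.0, abs=1e-9)
        assert ps.perimeter == pytest.approx(p, abs=1e-9)
        assert ps.Cx == pytest.approx(1.0, abs=1e-9)
        assert ps.Cy == pytest.approx(1 / 3, abs=1e-9)
        assert ps.filamentarity == pytest.approx(
            (p**2 - 4 * math.pi) / (p**2 + 4 * math.pi), abs=1e-9
        )

    def test_disjoint_tents_summed_as_multipolygon(self):
        # two unit tents: areas add, perimeters add, centroid area-weighted
        ps = landscape_polygon(make_diagram([(0, 2), (10, 12)]), 1)
        assert ps.area == pytest.approx(2.0, abs=1e-9)
        assert ps.perimeter == pytest.approx(2 * (2 + 2 * math.sqrt(2)), abs=1e-9)
        assert ps.Cx == pytest.approx(6.0, abs=1e-9)  # mean of midlives 1 and 11
        assert ps.Cy == pytest.approx(1 / 3, abs=1e-9)

    def test_degenerate_landscape_reports_zero_descriptors(self):
        ps = landscape_polygon(make_diagram([(0, 2)]), 3)
        assert ps.degenerate
        assert ps.as_tuple() == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_filamentarity_consistency(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ps = landscape_polygon(random_diagram(rng, 15), 2)
            expected = (ps.perimeter**2 - 4 * math.pi * ps.area) / (
                ps.perimeter**2 + 4 * math.pi * ps.area
            )
            assert ps.filamentarity == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= ps.filamentarity <= 1.0


class TestConvexPeel:
    def square_cloud(self):
        # 4 extreme corners (in death >= birth half-plane) plus 96 interior
        corners = [(0, 2), (0, 3), (1, 2), (1, 3)]
        rng = np.random.default_rng(6)
        interior = np.stack(
            [rng.uniform(0.2, 0.8, 96), rng.uniform(2.2, 2.8, 96)], axis=1
        )
        return make_diagram(corners + interior.tolist())

    def test_proportion_one_is_plain_convex_hull(self):
        dgm = self.square_cloud()
        ps = convex_peel(dgm, 1.0)
        assert ps.area == pytest.approx(1.0, abs=1e-9)
        assert ps.perimeter == pytest.approx(4.0, abs=1e-9)

    def test_no_peel_when_removal_would_drop_below_proportion(self):
        # removing the 4 hull corners would leave 96 < ceil(0.99 * 100) = 99
        ps = convex_peel(self.square_cloud(), 0.99)
        assert ps.area == pytest.approx(1.0, abs=1e-9)
        assert ps.perimeter == pytest.approx(4.0, abs=1e-9)
        assert ps.filamentarity == pytest.approx(
            (16 - 4 * math.pi) / (16 + 4 * math.pi), abs=1e-9
        )

    def test_peel_areas_non_increasing_with_depth(self):
        dgm = random_diagram(np.random.default_rng(7), 500)
        areas = [convex_peel(dgm, p).area for p in (1.0, 0.99, 0.95, 0.90)]
        assert all(a >= b - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_peel_nesting(self):
        dgm = random_diagram(np.random.default_rng(8), 300)
        outer = peel_polygon(dgm, 0.99)
        inner = peel_polygon(dgm, 0.90)
        assert outer.buffer(1e-9).contains(inner)

    def test_degenerate_clouds_rejected(self):
        with pytest.raises(DegenerateCloudError):
            convex_peel(make_diagram([(0, 1), (1, 2)]), 0.9)
        with pytest.raises(DegenerateCloudError):
            convex_peel(make_diagram([(0, 1), (1, 2), (2, 3)]), 0.9)  # collinear

    def test_shift_equivariance(self):
        dgm = random_diagram(np.random.default_rng(9), 100)
        delta = 2.5
        shifted = make_diagram(dgm.pairs + delta)
        for p in (0.99, 0.95, 0.90):
            a, b = convex_peel(dgm, p), convex_peel(shifted, p)
            assert b.Cx == pytest.approx(a.Cx + delta, abs=1e-9)
            assert b.Cy == pytest.approx(a.Cy + delta, abs=1e-9)
            assert b.area == pytest.approx(a.area, abs=1e-9)
            assert b.perimeter == pytest.approx(a.perimeter, abs=1e-9)
            assert b.filamentarity == pytest.approx(a.filamentarity, abs=1e-9)


class TestPolygonSummary:
    def test_unit_square(self):
        ps = polygon_summary(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert (ps.Cx, ps.Cy, ps.area, ps.perimeter) == (0.5, 0.5, 1.0, 4.0)
        assert ps.filamentarity == pytest.approx((16 - 4 * math.pi) / (16 + 4 * math.pi))

    def test_regular_polygon_filamentarity_vanishes(self):
        ts = np.linspace(0, 2 * math.pi, 2000, endpoint=False)
        ps = polygon_summary(Polygon(np.stack([np.cos(ts), np.sin(ts)], axis=1)))
        assert ps.filamentarity == pytest.approx(0.0, abs=1e-5)

    def test_zero_area_polygon_is_degenerate_with_limit_filamentarity(self):
        ps = polygon_summary(Polygon([(0, 0), (1, 0), (2, 0)]))
        assert ps.degenerate and ps.filamentarity == 1.0
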