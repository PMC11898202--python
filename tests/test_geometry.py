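import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigtherm.geometry import (
    DegenerateBoxError,
    GeometryError,
    Line2D,
    OrientedBox,
    ParallelLinesError,
    box_from_center,
    canonicalize,
    center_distance,
    extreme_vertices,
    line_intersection,
    line_through,
    nearest_vertex_pair,
    polar_angle,
    rasterize,
    rasterize_mask,
    rotated_iou,
    shoelace_area,
)

from conftest import random_box, unit_square


class TestCanonicalize:
    def test_axis_aligned_square_starts_at_min_yx(self):
        v = canonicalize([(10, 0), (0, 0), (0, 10), (10, 10)])
        assert tuple(v[0]) == (0, 0)
        # positive shoelace orientation in image coordinates
        x, y = v[:, 0], v[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0

    def test_idempotent(self, rng):
        for _ in range(50):
            v = random_box(rng).vertices
            assert np.array_equal(canonicalize(v), canonicalize(canonicalize(v)))

    def test_area_preserved_under_reordering(self, rng):
        for _ in range(50):
            box = random_box(rng)
            shuffled = box.vertices[rng.permutation(4)]
            assert shoelace_area(canonicalize(shuffled)) == pytest.approx(box.area)

    @pytest.mark.parametrize("bad", [
        [(0, 0), (1, 1), (2, 2), (3, 3)],          # collinear
        [(0, 0), (0, 0), (1, 0), (1, 1)],          # duplicate
        [(0, 0), (10, 0), (10, 10), (4, 4)],       # concave (point inside hull)
    ])
    def test_degenerate_rejected(self, bad):
        with pytest.raises(DegenerateBoxError):
            canonicalize(bad)


class TestCenter:
    def test_square_center(self):
        box = OrientedBox(np.array([(0, 0), (10, 0), (10, 10), (0, 10)], dtype=float))
        assert np.allclose(box.center, (5, 5))

    def test_rotated_rectangle_center_recovered(self):
        box = box_from_center((100, 50), 40, 8, 30.0)
        assert np.allclose(box.center, (100, 50))

    def test_invariant_under_vertex_reordering(self, rng):
        box = random_box(rng)
        shuffled = OrientedBox(box.vertices[rng.permutation(4)])
        assert np.allclose(box.center, shuffled.center)


class TestCenterDistance:
    def test_three_four_five(self):
        a = box_from_center((0, 0), 4, 2, 0)
        b = box_from_center((3, 4), 4, 2, 0)
        assert center_distance(a, b) == pytest.approx(5.0)
        assert center_distance(b, a) == pytest.approx(5.0)

    def test_identical_boxes(self, rng):
        box = random_box(rng)
        assert center_distance(box, box) == 0.0


class TestVertexSelection:
    def test_nearest_pair_matches_brute_force(self, rng):
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            p1, p2 = nearest_vertex_pair(a, b)
            best = min(
                ((np.linalg.norm(va - vb), tuple(va), tuple(vb))
                 for va in a.vertices for vb in b.vertices),
                key=lambda t: t[0])
            assert np.linalg.norm(p1 - p2) == pytest.approx(best[0])

    def test_tie_broken_by_canonical_index(self):
        a = unit_square()
        b = a.translated((1.0, 0.0))  # shares edge x=1; two vertex pairs at distance 0
        p1, p2 = nearest_vertex_pair(a, b)
        # lowest canonical index in a wins: a's cycle starts at (0,0), so the
        # first touching vertex encountered is (1,0) at index 1 of a
        assert tuple(p1) == (1.0, 0.0)
        assert tuple(p2) == (1.0, 0.0)

    def test_translation_equivariance(self, rng):
        a, b = random_box(rng), random_box(rng)
        p1, p2 = nearest_vertex_pair(a, b)
        q1, q2 = nearest_vertex_pair(a.translated((7.5, -3.25)), b.translated((7.5, -3.25)))
        assert np.allclose(q1, p1 + (7.5, -3.25))
        assert np.allclose(q2, p2 + (7.5, -3.25))

    def test_extreme_vertices_unit_square(self):
        p_min, p_max = extreme_vertices(unit_square(), (0.0, 0.0))
        assert tuple(p_min) == (0.0, 0.0)
        assert tuple(p_max) == (1.0, 1.0)

    def test_extreme_vertices_tie_rule_at_center(self):
        box = unit_square()
        p_min, p_max = extreme_vertices(box, (0.5, 0.5))
        # all four vertices equidistant: the canonical first vertex wins both
        assert np.array_equal(p_min, box.vertices[0])
        assert np.array_equal(p_max, box.vertices[0])

    def test_extreme_vertices_matches_brute_force(self, rng):
        for _ in range(100):
            box = random_box(rng)
            base = rng.uniform(0, 250, 2)
            p_min, p_max = extreme_vertices(box, base)
            dists = [np.linalg.norm(v - base) for v in box.vertices]
            assert np.linalg.norm(p_min - base) == pytest.approx(min(dists))
            assert np.linalg.norm(p_max - base) == pytest.approx(max(dists))


class TestLines:
    def test_points_satisfy_line_equation(self, rng):
        for _ in range(100):
            p, q = rng.uniform(-50, 50, 2), rng.uniform(-50, 50, 2)
            if np.allclose(p, q):
                continue
            line = line_through(p, q)
            assert abs(line.signed_distance(p)) < 1e-9
            assert abs(line.signed_distance(q)) < 1e-9

    def test_vertical_line(self):
        line = line_through((3, 0), (3, 5))
        assert line.b == pytest.approx(0.0)
        assert abs(line.signed_distance((3, 123.0))) < 1e-9

    def test_direction_independent(self, rng):
        p, q = (2.0, -1.0), (5.5, 3.0)
        l1, l2 = line_through(p, q), line_through(q, p)
        assert (l1.a, l1.b, l1.c) == pytest.approx((l2.a, l2.b, l2.c))

    def test_identical_points_rejected(self):
        with pytest.raises(GeometryError):
            line_through((1, 1), (1, 1))

    def test_intersection_of_crossing_lines(self):
        l1 = line_through((0, 0), (1, 1))       # y = x
        l2 = line_through((0, 2), (2, 0))       # y = -x + 2
        assert np.allclose(line_intersection(l1, l2), (1, 1))

    def test_intersection_vertical_horizontal(self):
        l1 = line_through((3, 0), (3, 1))       # x = 3
        l2 = line_through((0, 4), (1, 4))       # y = 4
        assert np.allclose(line_intersection(l1, l2), (3, 4))

    def test_parallel_lines_raise(self):
        l1 = line_through((0, 0), (1, 1))
        l2 = line_through((0, 1), (1, 2))
        with pytest.raises(ParallelLinesError):
            line_intersection(l1, l2)


class TestPolarAngle:
    def test_axis_cases(self):
        # directly above the origin in the image = smaller y = 90 degrees
        assert polar_angle((0, -1), (0, 0)).angle == pytest.approx(90.0)
        assert polar_angle((1, 0), (0, 0)).angle == pytest.approx(0.0)
        assert polar_angle((0, 1), (0, 0)).angle == pytest.approx(270.0)

    def test_radius(self):
        pp = polar_angle((3, -4), (0, 0))
        assert pp.radius == pytest.approx(5.0)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=60, derandomize=True)
    def test_antipode_adds_180(self, dx, dy):
        if math.hypot(dx, dy) < 1e-6:
            return
        a = polar_angle((dx, dy), (0, 0)).angle
        b = polar_angle((-dx, -dy), (0, 0)).angle
        assert (b - a) % 360.0 == pytest.approx(180.0, abs=1e-6)

    def test_rotation_equivariance(self, rng):
        origin = np.array([10.0, 20.0])
        for _ in range(50):
            p = origin + rng.uniform(-40, 40, 2)
            if np.linalg.norm(p - origin) < 1e-3:
                continue
            alpha = float(rng.uniform(0, 360))
            a0 = polar_angle(p, origin).angle
            # rotate p about origin by alpha in the y-up sense
            rad = math.radians(alpha)
            v = p - origin
            vy_up = np.array([v[0], -v[1]])
            rot = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]]) @ vy_up
            p_rot = origin + np.array([rot[0], -rot[1]])
            a1 = polar_angle(p_rot, origin).angle
            assert (a1 - a0) % 360.0 == pytest.approx(alpha % 360.0, abs=1e-6)

    def test_origin_rejected(self):
        with pytest.raises(GeometryError):
            polar_angle((5, 5), (5, 5))


class TestRotatedIoU:
    def test_identical_boxes(self, rng):
        box = random_box(rng)
        assert rotated_iou(box, box) == pytest.approx(1.0)

    def test_offset_squares(self):
        a = box_from_center((5, 5), 10, 10, 0)
        b = box_from_center((10, 5), 10, 10, 0)
        assert rotated_iou(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            iou = rotated_iou(a, b)
            assert 0.0 <= iou <= 1.0
            assert iou == pytest.approx(rotated_iou(b, a))

    def test_rotated_vs_axis_aligned_matches_grid_oracle(self):
        a = box_from_center((10, 10), 8, 8, 0)
        b = box_from_center((10, 10), 8, 8, 45)
        assert rotated_iou(a, b) == pytest.approx(_grid_iou(a, b), abs=1e-3)


def _grid_iou(a, b, h=0.01):
    """Dense point-sampling IoU, independent of the polygon-clipping route."""
    v = np.vstack([a.vertices, b.vertices]).astype(np.float32)
    lo, hi = v.min(axis=0) - 0.25, v.max(axis=0) + 0.25
    xs = np.arange(lo[0], hi[0], h, dtype=np.float32)[None, :]
    ys = np.arange(lo[1], hi[1], h, dtype=np.float32)[:, None]

    def inside(box):
        m = None
        vv = box.vertices
        for k in range(4):
            p, q = vv[k], vv[(k + 1) % 4]
            hp = (q[0] - p[0]) * (ys - p[1]) - (q[1] - p[1]) * (xs - p[0]) >= 0
            m = hp if m is None else (m & hp)
        return m

    ia, ib = inside(a), inside(b)
    either = np.count_nonzero(ia | ib)
    return np.count_nonzero(ia & ib) / either if either else 0.0


class TestRasterize:
    def test_exact_pixel_cover(self):
        box = OrientedBox(np.array([(0, 0), (2, 0), (2, 3), (0, 3)], dtype=float))
        pixels = rasterize(box, (10, 10))
        assert len(pixels) == 6  # rows 0-2 x cols 0-1
        assert set(map(tuple, pixels)) == {(r, c) for r in range(3) for c in range(2)}

    def test_box_outside_frame_is_empty(self):
        box = box_from_center((500, 500), 20, 10, 30)
        assert len(rasterize(box, (100, 100))) == 0
        assert not rasterize_mask(box, (100, 100)).any()

    def test_count_close_to_area(self, rng):
        for _ in range(50):
            box = random_box(rng, center_lo=40, center_hi=200)
            n = len(rasterize(box, (288, 384)))
            perimeter = sum(np.linalg.norm(box.vertices[k] - box.vertices[(k + 1) % 4])
                            for k in range(4))
            assert abs(n - box.area) <= perimeter


class TestLine2D:
    def test_normalization(self):
        line = Line2D(3.0, 4.0, 10.0)
        assert line.a**2 + line.b**2 == pytest.approx(1.0)
        assert line.a == pytest.approx(0.6)

    def test_zero_normal_rejected(self):
        with pytest.raises(GeometryError):
            Line2D(0.0, 0.0, 1.0)
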