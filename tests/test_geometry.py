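"""Geometry: boundary extraction, constrained ellipse fitting, tangents, AoP."""

import math

import numpy as np
import pytest

from aopnet import geometry as G
from aopnet.geometry import (
    AoPKeyPoints,
    AoPStatus,
    EllipseFitError,
    EmptyClassError,
    GeometricEllipse,
    Point2D,
    TangentError,
)


def brute_force_tangents(p: Point2D, e: GeometricEllipse, n: int = 720_000):
    """Oracle: scan densely sampled boundary points for extremal view angles."""
    pts = e.boundary_points(n)
    d = pts - np.array([p.x, p.y])
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return pts[np.argmin(ang)], pts[np.argmax(ang)]


class TestMaskToBoundary:
    def test_full_3x3_block_excludes_center(self):
        mask = np.ones((3, 3), dtype=np.uint8)
        pts = G.mask_to_boundary(mask, 1)
        assert len(pts) == 8
        assert [1.0, 1.0] not in pts.tolist()

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 3] = 1
        pts = G.mask_to_boundary(mask, 1)
        assert pts.tolist() == [[3.0, 2.0]]

    def test_largest_component_only(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[1:6, 1:5] = 1  # 20 pixels
        mask[8:9, 7:12] = 1  # 5 pixels
        pts = G.mask_to_boundary(mask, 1)
        # oracle: boundary of the 20-px block computed exhaustively
        expected = {
            (x, y)
            for y in range(1, 6)
            for x in range(1, 5)
            if y in (1, 5) or x in (1, 4)
        }
        assert {(int(x), int(y)) for x, y in pts} == expected

    def test_empty_class_raises(self):
        with pytest.raises(EmptyClassError):
            G.mask_to_boundary(np.zeros((4, 4), dtype=np.uint8), 1)


class TestFitEllipse:
    def test_unit_circle_symmetry(self):
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        conic = G.fit_ellipse(np.column_stack([np.cos(t), np.sin(t)]))
        assert conic.A == pytest.approx(conic.C_coef, abs=1e-9)
        assert conic.B == pytest.approx(0.0, abs=1e-9)
        assert conic.D_coef == pytest.approx(0.0, abs=1e-9)
        assert conic.E == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery(self):
        e = GeometricEllipse(Point2D(256, 192), 120, 70, math.radians(30))
        fit = G.conic_to_geometric(G.fit_ellipse(e.boundary_points(100)))
        assert fit.center.x == pytest.approx(256, rel=1e-6)
        assert fit.center.y == pytest.approx(192, rel=1e-6)
        assert fit.semi_major == pytest.approx(120, rel=1e-6)
        assert fit.semi_minor == pytest.approx(70, rel=1e-6)
        assert fit.theta == pytest.approx(math.radians(30), rel=1e-6)

    def test_noisy_center_recovery(self):
        rng = np.random.default_rng(42)
        e = GeometricEllipse(Point2D(256, 192), 120, 70, math.radians(30))
        pts = e.boundary_points(100) + rng.normal(0, 1.0, size=(100, 2))
        fit = G.conic_to_geometric(G.fit_ellipse(pts))
        assert np.hypot(fit.center.x - 256, fit.center.y - 192) < 1.0

    def test_constraint_normalization(self, rng):
        for _ in range(20):
            e = GeometricEllipse(
                Point2D(rng.uniform(-50, 50), rng.uniform(-50, 50)),
                rng.uniform(20, 80), rng.uniform(5, 20), rng.uniform(0, math.pi - 1e-6),
            )
            conic = G.fit_ellipse(e.boundary_points(60))
            assert abs(4 * conic.A * conic.C_coef - conic.B**2 - 1) < 1e-8

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0), (1, 1), (2, 2), (3, 3)],  # too few
            [(i, 2 * i) for i in range(10)],  # collinear
        ],
    )
    def test_degenerate_input_raises(self, points):
        with pytest.raises(EllipseFitError):
            G.fit_ellipse(points)


class TestConicConversion:
    def test_unit_circle(self):
        conic = G.ConicCoefficients(0.5, 0.0, 0.5, 0.0, 0.0, -0.5)
        e = G.conic_to_geometric(conic)
        assert (e.center.x, e.center.y) == pytest.approx((0, 0), abs=1e-12)
        assert e.semi_major == pytest.approx(1.0)
        assert e.semi_minor == pytest.approx(1.0)

    def test_axis_aligned(self):
        # x^2/4 + y^2 = 1, rescaled to satisfy 4AC - B^2 = 1
        conic = G.geometric_to_conic(GeometricEllipse(Point2D(0, 0), 2, 1, 0.0))
        e = G.conic_to_geometric(conic)
        assert e.semi_major == pytest.approx(2.0, rel=1e-12)
        assert e.semi_minor == pytest.approx(1.0, rel=1e-12)
        assert e.theta == 0.0

    def test_round_trip(self):
        e = GeometricEllipse(Point2D(10, -5), 7, 3, math.radians(100))
        back = G.conic_to_geometric(G.geometric_to_conic(e))
        assert back.center.x == pytest.approx(10, abs=1e-9)
        assert back.center.y == pytest.approx(-5, abs=1e-9)
        assert back.semi_major == pytest.approx(7, abs=1e-9)
        assert back.semi_minor == pytest.approx(3, abs=1e-9)
        assert 0 <= back.theta < math.pi
        assert back.theta == pytest.approx(math.radians(100), abs=1e-9)

    def test_degenerate_conic_rejected(self):
        with pytest.raises(G.DegenerateConicError):
            G.ConicCoefficients(1.0, 0.0, -1.0, 0.0, 0.0, 0.0)  # hyperbola


class TestKeyPoints:
    def test_circle_tie_break_theta_zero(self):
        e = G.conic_to_geometric(G.geometric_to_conic(GeometricEllipse(Point2D(0, 0), 2, 2, 1.0)))
        assert e.theta == 0.0
        p1, p2 = G.major_axis_endpoints(e)
        assert (p1.x, p1.y) == pytest.approx((-2, 0), abs=1e-9)
        assert (p2.x, p2.y) == pytest.approx((2, 0), abs=1e-9)

    def test_major_axis_endpoints_rotated(self):
        e = GeometricEllipse(Point2D(256, 192), 120, 70, math.radians(30))
        p1, p2 = G.major_axis_endpoints(e)
        dx, dy = 120 * math.cos(math.radians(30)), 120 * math.sin(math.radians(30))
        assert (p1.x, p1.y) == pytest.approx((256 - dx, 192 - dy))
        assert (p2.x, p2.y) == pytest.approx((256 + dx, 192 + dy))

    def test_label_endpoints_by_proximity(self):
        up, lp = G.label_endpoints(Point2D(0, 0), Point2D(10, 0), Point2D(20, 5))
        assert (up.x, up.y) == (0, 0)
        assert (lp.x, lp.y) == (10, 0)

    def test_label_endpoints_tie_larger_x(self):
        up, lp = G.label_endpoints(Point2D(-3, 0), Point2D(3, 0), Point2D(0, 7))
        assert lp.x == 3

    def test_phantom_designated_inferior_endpoint(self, small_phantoms):
        for s in small_phantoms:
            ps = s.spec.ps_ellipse()
            fh = s.spec.fh_ellipse()
            p1, p2 = G.major_axis_endpoints(ps)
            _up, lp = G.label_endpoints(p1, p2, fh.center)
            assert (lp.x, lp.y) == pytest.approx((s.gt_keypoints.Lp.x, s.gt_keypoints.Lp.y))


class TestTangents:
    def test_classic_circle_construction(self):
        t1, t2 = G.tangent_points(Point2D(2, 0), GeometricEllipse(Point2D(0, 0), 1, 1, 0.0))
        got = sorted([(t1.x, t1.y), (t2.x, t2.y)], key=lambda p: p[1])
        assert got[0] == pytest.approx((0.5, -math.sqrt(3) / 2))
        assert got[1] == pytest.approx((0.5, math.sqrt(3) / 2))

    def test_symmetry_on_major_axis(self):
        e = GeometricEllipse(Point2D(0, 0), 5, 2, 0.0)
        t1, t2 = G.tangent_points(Point2D(9, 0), e)
        assert t1.x == pytest.approx(t2.x)
        assert t1.y == pytest.approx(-t2.y)

    def test_brute_force_oracle_general_ellipse(self):
        e = GeometricEllipse(Point2D(300, 200), 110, 85, math.radians(20))
        p = Point2D(80, 60)
        t1, t2 = G.tangent_points(p, e)
        b1, b2 = brute_force_tangents(p, e)
        got = sorted([(t1.x, t1.y), (t2.x, t2.y)])
        exp = sorted([tuple(b1), tuple(b2)])
        for g, x in zip(got, exp):
            assert np.hypot(g[0] - x[0], g[1] - x[1]) < 0.1

    def test_tangency_condition_and_half_plane(self):
        e = GeometricEllipse(Point2D(50, 40), 30, 18, 0.7)
        p = Point2D(-20, 90)
        conic = G.geometric_to_conic(e)
        boundary = e.boundary_points(5000)
        for t in G.tangent_points(p, e):
            assert abs(conic.evaluate(t)) < 1e-8
            # all boundary points on one side of the line (p, t)
            d = np.array([t.x - p.x, t.y - p.y])
            n = np.array([-d[1], d[0]])
            signed = (boundary - np.array([p.x, p.y])) @ n
            assert (signed >= -1e-6 * np.abs(signed).max()).all() or (
                signed <= 1e-6 * np.abs(signed).max()
            ).all()

    def test_inside_point_raises(self):
        with pytest.raises(TangentError):
            G.tangent_points(Point2D(0, 0), GeometricEllipse(Point2D(0, 0), 2, 1, 0.0))

    def test_select_tangent_max_angle(self):
        tp = G.select_tangent(Point2D(0, -10), Point2D(0, 0), Point2D(5, 5), Point2D(5, -5))
        assert (tp.x, tp.y) == (5, 5)

    def test_select_tangent_tie_larger_x(self):
        tp = G.select_tangent(Point2D(0, -10), Point2D(0, 0), Point2D(5, 5), Point2D(-5, 5))
        assert tp.x == 5


class TestComputeAoP:
    @pytest.mark.parametrize(
        "tp,expected",
        [((1, 0), 90.0), ((0, 1), 180.0), ((1, 1), 135.0)],
    )
    def test_reference_angles(self, tp, expected):
        k = AoPKeyPoints(Point2D(0, -1), Point2D(0, 0), Point2D(*tp))
        assert G.compute_aop(k) == pytest.approx(expected)

    def test_zero_length_ray_raises(self):
        with pytest.raises(G.GeometryError):
            G.compute_aop(AoPKeyPoints(Point2D(0, 0), Point2D(0, 0), Point2D(1, 0)))

    def test_similarity_invariance(self, rng):
        for _ in range(25):
            pts = rng.uniform(-100, 100, size=(3, 2))
            if np.hypot(*(pts[0] - pts[1])) < 1e-3 or np.hypot(*(pts[2] - pts[1])) < 1e-3:
                continue
            base = G.compute_aop(AoPKeyPoints(*[Point2D(*p) for p in pts]))
            ang = rng.uniform(0, 2 * np.pi)
            s = rng.uniform(0.1, 10)
            shift = rng.uniform(-50, 50, size=2)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            moved = (pts @ R.T) * s + shift
            out = G.compute_aop(AoPKeyPoints(*[Point2D(*p) for p in moved]))
            assert out == pytest.approx(base, abs=1e-9)


class TestMeasureFromMask:
    def test_empty_class_status(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[10:30, 10:30] = 2
        assert G.measure_aop_from_mask(mask).status == AoPStatus.empty_class

    def test_phantom_agreement(self, default_phantom):
        r = G.measure_aop_from_mask(default_phantom.mask)
        assert r.status == AoPStatus.ok
        assert r.aop_deg == pytest.approx(default_phantom.gt_aop_deg, abs=2.0)

    def test_rotation_consistency(self, default_phantom):
        base = G.measure_aop_from_mask(default_phantom.mask)
        rot = G.measure_aop_from_mask(np.rot90(default_phantom.mask))
        assert rot.status == AoPStatus.ok
        assert rot.aop_deg == pytest.approx(base.aop_deg, abs=0.5)

    def test_determinism(self, default_phantom):
        a = G.measure_aop_from_mask(default_phantom.mask)
        b = G.measure_aop_from_mask(default_phantom.mask)
        assert a == b

    def test_measurement_records_ellipses(self, default_phantom):
        r = G.measure_aop_from_mask(default_phantom.mask)
        ps = default_phantom.spec.ps_ellipse()
        assert r.ps_ellipse.semi_major == pytest.approx(ps.semi_major, rel=0.1)
        assert 0 < r.aop_deg <= 180
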