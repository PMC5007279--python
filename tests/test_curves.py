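import numpy as np
import pytest
from hypothesis import given, strategies as st

from spinehough.curves import (
    EllipseParams,
    ThreeConvexityParams,
    WorkingFrame,
    ellipse_residual,
    point_inside,
    sample_curve,
    three_convexity_area,
    three_convexity_radius,
    three_convexity_residual,
)

# strategies over the numerically meaningful parameter range
a_vals = st.floats(0.1, 10.0)
b_vals = st.floats(-0.9, 0.9)
angles = st.floats(0.0, 2 * np.pi)


class TestThreeConvexity:
    def test_circle_degenerate_case(self):
        # b = 0 collapses the family to the circle of radius a
        p = ThreeConvexityParams(a=10.0, b=0.0)
        assert three_convexity_residual((10.0, 0.0), p) == pytest.approx(0.0)
        theta = np.linspace(0, 2 * np.pi, 100)
        assert np.allclose(three_convexity_radius(theta, p), 10.0)

    def test_center_is_degenerate_root(self):
        p = ThreeConvexityParams(a=3.0, b=0.4)
        assert three_convexity_residual((0.0, 0.0), p) == 0.0

    def test_polar_point_on_curve(self):
        # r(0) = a/(1+b) = 10/1.2
        p = ThreeConvexityParams(a=10.0, b=0.2)
        r0 = three_convexity_radius(0.0, p)
        assert r0 == pytest.approx(10.0 / 1.2)
        assert abs(three_convexity_residual((r0, 0.0), p)) < 1e-8 * p.a**6

    def test_radius_at_lobe_maximum(self):
        # cos 3θ = −1 at θ = π/3: r = a/(1−b)
        p = ThreeConvexityParams(a=10.0, b=0.2)
        assert three_convexity_radius(np.pi / 3, p) == pytest.approx(12.5)

    @pytest.mark.parametrize("a,b", [(0.0, 0.1), (-1.0, 0.1), (1.0, 1.0),
                                     (1.0, -1.5)])
    def test_invalid_parameters_rejected(self, a, b):
        with pytest.raises(ValueError):
            ThreeConvexityParams(a=a, b=b)

    @given(a=a_vals, b=b_vals, theta=angles)
    def test_polar_form_satisfies_implicit_equation(self, a, b, theta):
        p = ThreeConvexityParams(a=a, b=b)
        r = three_convexity_radius(theta, p)
        pt = (r * np.cos(theta), r * np.sin(theta))
        assert abs(three_convexity_residual(pt, p)) < 1e-8 * a**6

    @given(a=a_vals, b=b_vals, theta=angles)
    def test_three_fold_symmetry(self, a, b, theta):
        p = ThreeConvexityParams(a=a, b=b)
        r1 = three_convexity_radius(theta, p)
        r2 = three_convexity_radius(theta + 2 * np.pi / 3, p)
        assert r1 == pytest.approx(r2, rel=1e-12)

    @given(a=st.floats(0.2, 2.0), b=st.floats(-0.6, 0.6))
    def test_area_closed_form_matches_polygon_integration(self, a, b):
        # shoelace over a dense boundary sampling
        pts = sample_curve(ThreeConvexityParams(a=a, b=b), 4096)
        x, y = pts[:, 0], pts[:, 1]
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert shoelace == pytest.approx(
            three_convexity_area(ThreeConvexityParams(a=a, b=b)), rel=5e-3)


class TestEllipse:
    @pytest.mark.parametrize("pt,expected", [
        ((2.0 + 1.5, 3.0), 0.0),        # vertex
        ((2.0, 3.0 + 0.5), 0.0),        # co-vertex
    ])
    def test_residual_zero_on_boundary(self, pt, expected):
        p = EllipseParams(a=1.5, b=0.5, c=2.0, d=3.0)
        assert ellipse_residual(pt, p) == pytest.approx(expected)

    def test_residual_at_center_is_minus_a2b2(self):
        p = EllipseParams(a=2.0, b=1.0, c=0.0, d=0.0)
        assert ellipse_residual((0.0, 0.0), p) == pytest.approx(-4.0)

    def test_invalid_semi_axes_rejected(self):
        with pytest.raises(ValueError):
            EllipseParams(a=-1.0, b=1.0)


class TestSampleCurve:
    def test_unit_circle_four_points(self):
        pts = sample_curve(EllipseParams(a=1.0, b=1.0), 4)
        expected = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        assert np.allclose(pts, expected, atol=1e-12)

    def test_three_convexity_samples_lie_on_curve(self):
        p = ThreeConvexityParams(a=10.0, b=0.2)
        pts = sample_curve(p, 360)
        res = three_convexity_residual(pts, p)
        assert np.max(np.abs(res)) < 1e-9 * p.a**6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sample_curve(EllipseParams(a=1.0, b=1.0), 2)


class TestPointInside:
    @pytest.mark.parametrize("params", [
        ThreeConvexityParams(a=10.0, b=0.2),
        EllipseParams(a=2.0, b=1.0, c=0.5, d=-0.5),
    ])
    def test_center_inside_far_point_outside(self, params):
        center = getattr(params, "center", None) or (params.c, params.d)
        assert point_inside(center, params)
        assert not point_inside((center[0] + 50.0, center[1]), params)

    def test_point_just_inside_lobe_maximum(self):
        # boundary radius at θ = π/3 is 12.5 for a=10, b=0.2
        p = ThreeConvexityParams(a=10.0, b=0.2)
        pt = 12.4 * np.array([np.cos(np.pi / 3), np.sin(np.pi / 3)])
        assert point_inside(pt, p)

    @given(a=a_vals, b=b_vals, seed=st.integers(0, 2**16))
    def test_inside_test_consistent_with_residual_sign(self, a, b, seed):
        p = ThreeConvexityParams(a=a, b=b)
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, 50)
        frac = rng.uniform(0.05, 2.0, 50)
        r_b = three_convexity_radius(theta, p)
        pts = (frac * r_b)[:, None] * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        inside = point_inside(pts, p)
        res = three_convexity_residual(pts, p)
        # strictly inside (excluding the origin neighbourhood) → negative
        strict = np.abs(frac - 1.0) > 1e-6
        assert np.all((res < 0)[inside & strict])
        assert np.all((res > 0)[~inside & strict])


class TestWorkingFrame:
    @given(ox=st.floats(-100, 100), oy=st.floats(-100, 100),
           scale=st.floats(0.1, 100),
           px=st.floats(-500, 500), py=st.floats(-500, 500))
    def test_round_trip_identity(self, ox, oy, scale, px, py):
        f = WorkingFrame(origin=(ox, oy), scale=scale)
        p = np.array([px, py])
        back = f.to_pixel(f.to_frame(p))
        assert np.allclose(back, p, atol=1e-9 * max(1.0, abs(px), abs(py)))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            WorkingFrame(origin=(0, 0), scale=0.0)
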