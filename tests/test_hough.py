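import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spinehough.curves import EllipseParams, ThreeConvexityParams, sample_curve
from spinehough.hough import (
    Accumulator,
    EdgePointSet,
    NoCurveFound,
    ParameterGrid,
    canal_grid,
    cord_grid,
    detect_canal,
    detect_cord,
    detect_edges,
    find_peak,
    vote,
)


def brute_force_canal(points, grid):
    """Independent scalar voting loop for the three-convexity family."""
    counts = np.zeros(grid.shape, dtype=np.int64)
    half = grid.side / 2
    for x, y in points:
        r = math.hypot(x, y)
        th = math.atan2(y, x)
        rc3 = r * math.cos(3 * th)
        for i, a in enumerate(grid.centers(0)):
            for j, b in enumerate(grid.centers(1)):
                if abs(r + rc3 * b - a) <= half * (1 + abs(rc3)):
                    counts[i, j] += 1
    return counts


def brute_force_ellipse(points, grid):
    """Independent scalar voting loop for the ellipse family."""
    counts = np.zeros(grid.shape, dtype=np.int64)
    half = grid.side / 2
    A, B, C, D = (grid.centers(k) for k in range(4))
    for x, y in points:
        for i, a in enumerate(A):
            for j, b in enumerate(B):
                for k, c in enumerate(C):
                    for l, d in enumerate(D):
                        xc, yd = x - c, y - d
                        F = (b * b) * (xc * xc) + (a * a) * (yd * yd) \
                            - (a * a) * (b * b)
                        tol = half * (
                            2 * a * abs(yd * yd - b * b)
                            + 2 * b * abs(xc * xc - a * a)
                            + 2 * (b * b) * abs(xc)
                            + 2 * (a * a) * abs(yd))
                        if abs(F) <= tol:
                            counts[i, j, k, l] += 1
    return counts


class TestParameterGrid:
    def test_cell_counts_and_centers(self):
        g = ParameterGrid(lower=(0.0, -0.5), upper=(0.6, 0.5), side=0.02)
        assert g.shape == (30, 50)
        assert g.centers(0)[0] == pytest.approx(0.01)
        assert g.cell_center((0, 0)) == pytest.approx((0.01, -0.49))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(lower=(0.5,), upper=(0.1,))
        with pytest.raises(ValueError):
            ParameterGrid(lower=(0.0,), upper=(1.0,), side=0.0)


class TestDetectEdges:
    def test_uniform_image_has_no_edges(self):
        assert len(detect_edges(np.full((32, 32), 3.0))) == 0

    def test_vertical_step_gives_vertical_line(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        pts = detect_edges(img).points
        assert len(pts) > 20
        assert np.ptp(pts[:, 0]) <= 1.0  # single vertical line

    def test_disk_edge_centroid_and_count(self):
        from skimage.draw import disk

        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 20)
        img[rr, cc] = 1.0
        pts = detect_edges(img).points
        centroid = pts.mean(axis=0)
        assert np.allclose(centroid, (32, 32), atol=0.5)
        assert abs(len(pts) - 2 * np.pi * 20) / (2 * np.pi * 20) < 0.15

    def test_degenerate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((8, 8)), low=0.5, high=0.1)


class TestVote:
    def test_single_point_single_cell(self):
        # one-cell grid centered at (a, b, c, d); vertex point (c+a, d)
        a, b, c, d = 0.31, 0.19, 0.01, -0.03
        grid = ParameterGrid(
            lower=(a - 0.01, b - 0.01, c - 0.01, d - 0.01),
            upper=(a + 0.01, b + 0.01, c + 0.01, d + 0.01), side=0.02)
        acc = vote(EdgePointSet([[c + a, d]]), grid, "ellipse")
        assert acc.counts.shape == (1, 1, 1, 1)
        assert acc.total == 1

    def test_empty_point_set_gives_zero_accumulator(self):
        acc = vote(EdgePointSet(np.empty((0, 2))), canal_grid(),
                   "three_convexity")
        assert acc.total == 0

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vote(EdgePointSet([[0.1, 0.1]]), canal_grid(), "ellipse")

    def test_sampled_ellipse_peak_at_truth(self):
        truth = EllipseParams(a=0.30, b=0.18, c=0.02, d=-0.04)
        pts = sample_curve(truth, 200)
        grid = ParameterGrid(lower=(0.1, 0.1, -0.1, -0.1),
                             upper=(0.5, 0.3, 0.1, 0.1), side=0.02)
        acc = vote(EdgePointSet(pts), grid, "ellipse")
        _, (a, b, c, d), _ = find_peak(acc)
        for est, tru in zip((a, b, c, d), (0.30, 0.18, 0.02, -0.04)):
            assert abs(est - tru) <= 0.02 + 1e-12

    def test_matches_brute_force_canal(self):
        rng = np.random.default_rng(1)
        pts = sample_curve(ThreeConvexityParams(a=0.35, b=0.15), 120)
        pts = np.vstack([pts, rng.uniform(-0.6, 0.6, (80, 2))])
        grid = canal_grid()
        acc = vote(EdgePointSet(pts), grid, "three_convexity")
        assert np.array_equal(acc.counts, brute_force_canal(pts, grid))

    def test_matches_brute_force_ellipse(self):
        rng = np.random.default_rng(2)
        pts = sample_curve(EllipseParams(0.15, 0.13, 0.01, -0.01), 140)
        pts = np.vstack([pts, rng.uniform(-0.2, 0.2, (60, 2))])
        grid = ParameterGrid(lower=(0.08, 0.08, -0.1, -0.1),
                             upper=(0.22, 0.22, 0.1, 0.1), side=0.02)
        acc = vote(EdgePointSet(pts), grid, "ellipse")
        assert np.array_equal(acc.counts, brute_force_ellipse(pts, grid))

    @given(seed=st.integers(0, 1000), n_extra=st.integers(1, 20))
    def test_adding_points_never_decreases_counts(self, seed, n_extra):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-0.5, 0.5, (15, 2))
        extra = rng.uniform(-0.5, 0.5, (n_extra, 2))
        grid = ParameterGrid(lower=(0.1, -0.3), upper=(0.5, 0.3), side=0.02)
        acc1 = vote(EdgePointSet(base), grid, "three_convexity")
        acc2 = vote(EdgePointSet(np.vstack([base, extra])), grid,
                    "three_convexity")
        assert np.all(acc2.counts >= acc1.counts)


class TestFindPeak:
    def test_single_nonzero_cell(self):
        grid = ParameterGrid(lower=(0.0, 0.0), upper=(0.2, 0.2), side=0.02)
        counts = np.zeros(grid.shape, dtype=np.int64)
        counts[3, 7] = 5
        idx, params, votes = find_peak(Accumulator(grid=grid, counts=counts))
        assert idx == (3, 7)
        assert votes == 5

    def test_tie_broken_by_lowest_lexicographic_index(self):
        grid = ParameterGrid(lower=(0.0, 0.0), upper=(0.2, 0.2), side=0.02)
        counts = np.zeros(grid.shape, dtype=np.int64)
        counts[3, 4] = 9
        counts[2, 7] = 9
        idx, _, _ = find_peak(Accumulator(grid=grid, counts=counts))
        assert idx == (2, 7)

    def test_all_zero_accumulator_raises(self):
        grid = ParameterGrid(lower=(0.0,), upper=(0.1,), side=0.02)
        with pytest.raises(NoCurveFound):
            find_peak(Accumulator(grid=grid))

    def test_exact_recovery_for_cell_centered_truth(self):
        # truth (0.35, 0.15) sits on cell centers of the default grid
        pts = sample_curve(ThreeConvexityParams(a=0.35, b=0.15), 300)
        acc = vote(EdgePointSet(pts), canal_grid(), "three_convexity")
        _, (a, b), _ = find_peak(acc)
        assert a == pytest.approx(0.35)
        assert b == pytest.approx(0.15)


class TestDetectors:
    def test_canal_recovery_from_sampled_curve(self):
        pts = sample_curve(ThreeConvexityParams(a=0.35, b=0.15), 100)
        params, votes = detect_canal(EdgePointSet(pts), canal_grid())
        assert abs(params.a - 0.35) <= 0.02
        assert abs(params.b - 0.15) <= 0.02
        assert votes >= 50

    def test_circular_canal_recovers_b_near_zero(self):
        pts = sample_curve(ThreeConvexityParams(a=0.35, b=1e-9), 100)
        params, _ = detect_canal(EdgePointSet(pts), canal_grid())
        assert abs(params.b) <= 0.02

    def test_too_few_points_raises(self):
        with pytest.raises(NoCurveFound):
            detect_canal(EdgePointSet([[0.3, 0.0]]), canal_grid())

    def test_cord_recovery_and_circular_cord(self):
        truth = EllipseParams(a=0.11, b=0.11, c=0.01, d=0.01)
        pts = sample_curve(truth, 80)
        params, _ = detect_cord(EdgePointSet(pts), cord_grid())
        assert abs(params.a - params.b) <= 0.02

    def test_empty_interior_raises(self):
        with pytest.raises(NoCurveFound):
            detect_cord(EdgePointSet(np.empty((0, 2))), cord_grid())
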