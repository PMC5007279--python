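"""Generalized Hough transform: edge detection, voting, and peak search.

The recognition scheme is the classical five-step one:

1. Canny edge detection extracts intensity discontinuities.
2. Each edge point is mapped to its Hough hypersurface in parameter space —
   the set of parameters whose curve passes through the point.
3. The parameter space is discretized into cells of side 0.02 (squares for
   the two-parameter canal family, hypercubes for the four-parameter
   ellipse family).
4. An accumulator counts, per cell, how many Hough hypersurfaces pass
   through it.
5. The recognized curve is the one at the accumulator maximum.

"Passing through a cell" is realized as a residual band: an edge point
votes for a cell iff the curve at the cell *center* passes within a
tolerance of the point, the tolerance being the first-order bound on the
boundary displacement induced by perturbing each parameter by half a cell
side.  For the canal family the on-curve constraint is exactly linear in
(a, b) — a point at polar coordinates (r, θ) lies on C_{a,b} iff
``a = r + b·r·cos3θ`` — so the bound is exact there and an on-curve point is
guaranteed to vote for the cell containing the true parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny as _canny

from .curves import EllipseParams, ThreeConvexityParams

__all__ = [
    "EdgePointSet",
    "ParameterGrid",
    "Accumulator",
    "NoCurveFound",
    "detect_edges",
    "vote",
    "find_peak",
    "detect_canal",
    "detect_cord",
    "canal_grid",
    "cord_grid",
]


class NoCurveFound(RuntimeError):
    """Raised when the accumulator carries no usable maximum."""


@dataclass(frozen=True)
class EdgePointSet:
    """Edge-point coordinates (N, 2) as (x, y), plus the slice they came from."""

    points: np.ndarray
    source_slice: int = -1

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[-1] != 2:
            raise ValueError(f"points must be (N, 2), got {pts.shape}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ParameterGrid:
    """Uniform discretization of the parameter space.

    ``lower``/``upper`` are per-dimension bounds; every dimension shares the
    same cell ``side`` (0.02 by default, the value used for both curve
    families).  Cell centers are ``lower + side·(i + ½)``.
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    side: float = 0.02

    def __post_init__(self) -> None:
        lo = tuple(float(v) for v in self.lower)
        hi = tuple(float(v) for v in self.upper)
        if len(lo) != len(hi):
            raise ValueError("lower/upper dimensionality mismatch")
        if not self.side > 0:
            raise ValueError(f"cell side must be > 0, got {self.side}")
        if any(h <= l for l, h in zip(lo, hi)):
            raise ValueError("upper bound must exceed lower bound in every dimension")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def ndim(self) -> int:
        return len(self.lower)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(
            int(math.ceil((h - l) / self.side - 1e-12))
            for l, h in zip(self.lower, self.upper)
        )

    def centers(self, dim: int) -> np.ndarray:
        n = self.shape[dim]
        return self.lower[dim] + self.side * (np.arange(n) + 0.5)

    def cell_center(self, index: tuple[int, ...]) -> tuple[float, ...]:
        return tuple(
            self.lower[d] + self.side * (i + 0.5) for d, i in enumerate(index)
        )


@dataclass
class Accumulator:
    """Integer vote counts over a :class:`ParameterGrid`."""

    grid: ParameterGrid
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(self.grid.shape, dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != self.grid.shape:
                raise ValueError("counts shape does not match grid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def detect_edges(image, sigma: float = 1.0, low: float = 0.1,
                 high: float = 0.3, source_slice: int = -1) -> EdgePointSet:
    """Canny edge detection; returns edge-pixel coordinates (x, y).

    Thresholds apply to the gradient magnitude of the (smoothed) image and
    must satisfy ``high >= low >= 0``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("image must be 2D with at least 2x2 pixels")
    if low < 0 or high < low:
        raise ValueError(f"need high >= low >= 0, got low={low}, high={high}")
    mask = _canny(image, sigma=sigma, low_threshold=low, high_threshold=high)
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)
    return EdgePointSet(points=pts, source_slice=source_slice)


def _vote_three_convexity(points: np.ndarray, grid: ParameterGrid) -> np.ndarray:
    """Vectorized voting for C_{a,b}.

    The on-curve constraint is linear: g(a, b) = r(1 + b·cos3θ) − a, with
    exact half-cell tolerance (s/2)·(1 + r·|cos3θ|).
    """
    a_c = grid.centers(0)
    b_c = grid.centers(1)
    counts = np.zeros(grid.shape, dtype=np.int64)
    half = grid.side / 2.0
    x = points[:, 0]
    y = points[:, 1]
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    rc3 = r * np.cos(3.0 * theta)
    # broadcast (npoints, na, nb)
    g = (r[:, None, None] + rc3[:, None, None] * b_c[None, None, :]
         - a_c[None, :, None])
    tol = half * (1.0 + np.abs(rc3))[:, None, None]
    counts += (np.abs(g) <= tol).sum(axis=0)
    return counts


def _vote_ellipse(points: np.ndarray, grid: ParameterGrid) -> np.ndarray:
    """Vectorized voting for E_{a,b,c,d} with the first-order tolerance.

    F = b²(x−c)² + a²(y−d)² − a²b²; tolerance
    (s/2)·(|∂F/∂a| + |∂F/∂b| + |∂F/∂c| + |∂F/∂d|) at the cell center.
    """
    A = grid.centers(0)
    B = grid.centers(1)
    C = grid.centers(2)
    D = grid.centers(3)
    A2 = A * A
    B2 = B * B
    half = grid.side / 2.0
    counts = np.zeros(grid.shape, dtype=np.int64)
    a4 = A[:, None, None, None]
    b4 = B[None, :, None, None]
    a2 = A2[:, None, None, None]
    b2 = B2[None, :, None, None]
    for x, y in points:
        xc = x - C  # (nc,)
        yd = y - D  # (nd,)
        X2 = (xc * xc)[None, None, :, None]
        Y2 = (yd * yd)[None, None, None, :]
        F = b2 * X2 + a2 * Y2 - a2 * b2
        tol = half * (
            2.0 * a4 * np.abs(Y2 - b2)
            + 2.0 * b4 * np.abs(X2 - a2)
            + 2.0 * b2 * np.abs(xc)[None, None, :, None]
            + 2.0 * a2 * np.abs(yd)[None, None, None, :]
        )
        counts += np.abs(F) <= tol
    return counts


def vote(points: EdgePointSet, grid: ParameterGrid, family: str) -> Accumulator:
    """Build the accumulator for ``points`` over ``grid``.

    ``family`` is ``"three_convexity"`` (2D grid) or ``"ellipse"`` (4D
    grid).  An empty point set yields a valid all-zero accumulator.
    """
    expected = {"three_convexity": 2, "ellipse": 4}
    if family not in expected:
        raise ValueError(f"unknown curve family {family!r}")
    if grid.ndim != expected[family]:
        raise ValueError(
            f"{family} requires a {expected[family]}-dimensional grid, "
            f"got {grid.ndim} dimensions"
        )
    pts = points.points
    if len(points) == 0:
        return Accumulator(grid=grid)
    if family == "three_convexity":
        counts = _vote_three_convexity(pts, grid)
    else:
        counts = _vote_ellipse(pts, grid)
    return Accumulator(grid=grid, counts=counts)


def find_peak(acc: Accumulator):
    """Locate the accumulator maximum.

    Returns ``(cell_index, cell_center_parameters, vote_count)``.  Ties are
    broken deterministically in two stages: the tied cell closest to the
    centroid of the tied set wins (an exactly-sampled curve produces a
    plateau of maximal cells symmetric about the true parameters, so the
    plateau center is the right representative), remaining ties fall back
    to the lowest lexicographic cell index.  An all-zero accumulator raises
    :class:`NoCurveFound`.
    """
    if acc.total == 0:
        raise NoCurveFound("accumulator holds no votes")
    peak = int(acc.counts.max())
    tied = np.argwhere(acc.counts == peak)
    if len(tied) == 1:
        index = tuple(int(i) for i in tied[0])
    else:
        centroid = tied.mean(axis=0)
        d2 = ((tied - centroid) ** 2).sum(axis=1)
        # stable lexicographic order of argwhere resolves residual ties
        index = tuple(int(i) for i in tied[int(np.argmin(d2))])
    return index, acc.grid.cell_center(index), int(acc.counts[index])


def canal_grid(a_range=(0.1, 0.7), b_range=(-0.5, 0.5), side=0.02) -> ParameterGrid:
    """Default canal parameter grid (a, b) in working units."""
    return ParameterGrid(lower=(a_range[0], b_range[0]),
                         upper=(a_range[1], b_range[1]), side=side)


def cord_grid(axis_range=(0.02, 0.4), center_range=(-0.3, 0.3),
              side=0.02) -> ParameterGrid:
    """Default cord ellipse grid (a, b, c, d) in working units."""
    return ParameterGrid(
        lower=(axis_range[0], axis_range[0], center_range[0], center_range[0]),
        upper=(axis_range[1], axis_range[1], center_range[1], center_range[1]),
        side=side,
    )


def detect_canal(points: EdgePointSet, grid: ParameterGrid,
                 min_points: int = 10, min_votes: int = 5):
    """Detect the canal curve: vote over (a, b) and take the peak.

    Returns ``(ThreeConvexityParams, vote_count)``; raises
    :class:`NoCurveFound` on too few edge points or too few votes.
    """
    if len(points) < min_points:
        raise NoCurveFound(
            f"only {len(points)} edge points (< {min_points}) for canal detection"
        )
    acc = vote(points, grid, "three_convexity")
    _, (a, b), votes = find_peak(acc)
    if votes < min_votes:
        raise NoCurveFound(f"canal peak has only {votes} votes (< {min_votes})")
    return ThreeConvexityParams(a=a, b=b), votes


def detect_cord(points_inside_canal: EdgePointSet, grid: ParameterGrid,
                min_points: int = 10, min_votes: int = 5):
    """Detect the cord ellipse among edge points inside the canal."""
    if len(points_inside_canal) < min_points:
        raise NoCurveFound(
            f"only {len(points_inside_canal)} edge points (< {min_points}) "
            f"for cord detection"
        )
    acc = vote(points_inside_canal, grid, "ellipse")
    _, (a, b, c, d), votes = find_peak(acc)
    if votes < min_votes:
        raise NoCurveFound(f"cord peak has only {votes} votes (< {min_votes})")
    return EllipseParams(a=a, b=b, c=c, d=d), votes
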