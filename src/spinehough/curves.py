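"""Algebraic curve families used to delineate the spinal canal and cord.

Two families are recognized on each axial CT slice:

* the *three-convexity* sextic ``C_{a,b}``,

  .. math:: (x^2+y^2)^3 = \\bigl(a(x^2+y^2) - b(x^3-3xy^2)\\bigr)^2,

  whose bounded lobe (for ``|b| < 1``) matches the trefoil-like cross-section
  of the vertebral canal.  In polar coordinates about its center the lobe is
  ``r(θ) = a / (1 + b·cos 3θ)``, which makes the three-fold symmetry explicit.

* the four-parameter ellipse ``E_{a,b,c,d}``,

  .. math:: b^2 (x-c)^2 + a^2 (y-d)^2 - a^2 b^2 = 0,

  which matches the cross-section of the spinal cord inside the canal.

The three-convexity family carries no translation parameters: it is always
detected in a *working frame* whose origin sits on a per-slice estimate of
the canal center and whose scale maps the expected canal radius to roughly
0.2–0.6 working units, so that the 0.02 accumulator cell side corresponds to
a few percent relative resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThreeConvexityParams",
    "EllipseParams",
    "WorkingFrame",
    "three_convexity_residual",
    "three_convexity_radius",
    "three_convexity_area",
    "ellipse_residual",
    "sample_curve",
    "point_inside",
]


@dataclass(frozen=True)
class ThreeConvexityParams:
    """Parameters of the three-convexity curve ``C_{a,b}``.

    ``a`` is the overall scale (mean radius) in working-frame units, ``b``
    the dimensionless convexity depth.  ``|b| < 1`` is required for the
    lobe to be bounded (the polar radius diverges otherwise).  ``center``
    places the family origin in the working frame; detection always uses
    ``(0, 0)`` and handles translation through the frame itself.
    """

    a: float
    b: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"scale parameter a must be > 0, got {self.a}")
        if not abs(self.b) < 1:
            raise ValueError(
                f"convexity parameter must satisfy |b| < 1 for a bounded "
                f"curve, got b={self.b}"
            )


@dataclass(frozen=True)
class EllipseParams:
    """Parameters of the ellipse ``E_{a,b,c,d}``: semi-axes ``a`` (along x)
    and ``b`` (along y), center ``(c, d)``; all in working-frame units."""

    a: float
    b: float
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(
                f"semi-axes must be > 0, got a={self.a}, b={self.b}"
            )


@dataclass(frozen=True)
class WorkingFrame:
    """Affine map between pixel coordinates and working-frame coordinates.

    ``origin`` is the pixel coordinate (x, y) mapped to (0, 0); ``scale`` is
    the length in pixels mapped to one working unit.
    """

    origin: tuple[float, float]
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"frame scale must be > 0, got {self.scale}")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map pixel coordinates (…, 2) to working-frame coordinates."""
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / self.scale

    def to_pixel(self, points: np.ndarray) -> np.ndarray:
        """Map working-frame coordinates (…, 2) back to pixel coordinates."""
        return np.asarray(points, dtype=float) * self.scale + np.asarray(self.origin)


def _split_xy(p, center=(0.0, 0.0)):
    p = np.asarray(p, dtype=float)
    x = p[..., 0] - center[0]
    y = p[..., 1] - center[1]
    return x, y


def three_convexity_residual(p, params: ThreeConvexityParams):
    """Signed residual of ``C_{a,b}`` at point(s) ``p``.

    Zero iff the point lies on the curve; strictly negative inside the
    bounded lobe (except at the center itself, an algebraic double root
    where the residual vanishes for every parameter choice).
    """
    x, y = _split_xy(p, params.center)
    r2 = x * x + y * y
    return r2**3 - (params.a * r2 - params.b * (x**3 - 3 * x * y * y)) ** 2


def three_convexity_radius(theta, params: ThreeConvexityParams):
    """Polar radius ``r(θ) = a / (1 + b·cos 3θ)`` of the bounded lobe."""
    theta = np.asarray(theta, dtype=float)
    return params.a / (1.0 + params.b * np.cos(3.0 * theta))


def three_convexity_area(params: ThreeConvexityParams) -> float:
    """Area enclosed by the lobe: ``π a² / (1 − b²)^{3/2}``.

    Follows from ``A = ½∫r(θ)²dθ`` with the standard integral
    ``∫₀^{2π} dφ/(1+b cosφ)² = 2π/(1−b²)^{3/2}``.
    """
    return float(np.pi * params.a**2 / (1.0 - params.b**2) ** 1.5)


def ellipse_residual(p, params: EllipseParams):
    """Signed residual ``b²(x−c)² + a²(y−d)² − a²b²``; negative inside."""
    x, y = _split_xy(p, (params.c, params.d))
    a, b = params.a, params.b
    return b * b * x * x + a * a * y * y - a * a * b * b


def sample_curve(params, n: int) -> np.ndarray:
    """Sample ``n`` points on the curve boundary, uniformly in θ ∈ [0, 2π).

    Returns an (n, 2) array of (x, y) coordinates in the same frame as the
    parameters.  ``n >= 3`` required.
    """
    if n < 3:
        raise ValueError(f"need at least 3 sample points, got {n}")
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if isinstance(params, ThreeConvexityParams):
        r = three_convexity_radius(theta, params)
        cx, cy = params.center
        return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    if isinstance(params, EllipseParams):
        return np.column_stack(
            [params.c + params.a * np.cos(theta), params.d + params.b * np.sin(theta)]
        )
    raise TypeError(f"unsupported curve parameters: {type(params).__name__}")


def point_inside(p, params) -> np.ndarray:
    """Strict inside test used to rasterize the binary masks.

    For the ellipse, inside means negative residual.  For the
    three-convexity lobe, the polar radius of the point is compared with
    the boundary radius along the same direction.
    """
    if isinstance(params, EllipseParams):
        return np.asarray(ellipse_residual(p, params) < 0)
    if isinstance(params, ThreeConvexityParams):
        x, y = _split_xy(p, params.center)
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        return np.asarray(r < three_convexity_radius(theta, params))
    raise TypeError(f"unsupported curve parameters: {type(params).__name__}")
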