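"""Per-slice canal/cord extraction over a CT volume, segments, masks, volumes.

The pipeline on each axial slice is: bone-window preprocessing → Canny edge
detection → working frame centered on a canal-center estimate → Hough
detection of the three-convexity canal curve → a second, narrow soft-tissue
window Canny pass restricted to the canal interior → Hough detection of the
cord ellipse → rasterization of both curves to binary masks.  The cord mask
is intersected with the canal mask so nesting holds by construction.

Slices are processed cranial→caudal; each slice's fitted canal center is
carried forward as the next slice's prior.  A per-slice failure contributes
empty masks and is recorded rather than aborting the run (low-dose CT
slices between vertebral bodies can be edge-poor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .curves import (
    EllipseParams,
    ThreeConvexityParams,
    WorkingFrame,
    point_inside,
    three_convexity_radius,
)
from .hough import (
    EdgePointSet,
    NoCurveFound,
    ParameterGrid,
    canal_grid,
    cord_grid,
    detect_canal,
    detect_cord,
    detect_edges,
)

logger = logging.getLogger("spinehough")

__all__ = [
    "ImageVolume",
    "SegmentDefinition",
    "SegmentationConfig",
    "SliceFit",
    "SegmentationResult",
    "SegmentationFailed",
    "partition_segments",
    "estimate_canal_center",
    "segment_slice",
    "segment_volume_run",
    "compute_volume",
    "rasterize_mask",
]

CERVICAL = "cervical"
DORSAL = "dorsal"


class SegmentationFailed(RuntimeError):
    """Raised when more than half the slices of a segment fail."""


@dataclass
class ImageVolume:
    """A 3D scalar grid: axial slices indexed cranial→caudal.

    ``data`` has shape (nslices, ny, nx); ``spacing`` is (slice thickness,
    row spacing, column spacing) in mm; ``modality`` is ``"CT"`` (Hounsfield
    units) or ``"PET"`` (activity concentration, kBq/mL).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


@dataclass(frozen=True)
class SegmentDefinition:
    """Anatomical segment boundaries as axial slice indices.

    Cervical covers ``[occiput_slice, c7_slice)`` (skull base to the plane
    adjacent to the caudal face of C7); dorsal covers ``[c7_slice,
    d12_slice]`` (that plane to the caudal face of D12, inclusive).  More
    caudal slices hold no spinal cord and are excluded.
    """

    occiput_slice: int
    c7_slice: int
    d12_slice: int

    def __post_init__(self) -> None:
        if not (self.occiput_slice < self.c7_slice <= self.d12_slice):
            raise ValueError(
                f"plane indices must satisfy occiput < c7 <= d12, got "
                f"{self.occiput_slice}, {self.c7_slice}, {self.d12_slice}"
            )

    def slices(self, segment: str) -> range:
        if segment == CERVICAL:
            return range(self.occiput_slice, self.c7_slice)
        if segment == DORSAL:
            return range(self.c7_slice, self.d12_slice + 1)
        raise ValueError(f"unknown segment {segment!r}")

    @property
    def analyzed(self) -> range:
        return range(self.occiput_slice, self.d12_slice + 1)

    def segment_of(self, slice_index: int) -> str:
        if slice_index in self.slices(CERVICAL):
            return CERVICAL
        if slice_index in self.slices(DORSAL):
            return DORSAL
        raise ValueError(f"slice {slice_index} outside the analyzed segments")


@dataclass
class SegmentationConfig:
    """Tunable settings of the per-slice detection chain.

    The frame scale (mm per working unit) makes the canal radius land around
    0.2–0.6 working units so that the 0.02 accumulator cell side is a few
    percent relative resolution.  Windows are HU clamp ranges; Canny
    thresholds apply to the gradient of the window-normalized image.
    """

    frame_scale_mm: float = 40.0
    bone_window: tuple[float, float] = (-100.0, 1500.0)
    soft_window: tuple[float, float] = (-50.0, 150.0)
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.3
    canal_a_range: tuple[float, float] = (0.1, 0.7)
    canal_b_range: tuple[float, float] = (-0.5, 0.5)
    cord_axis_range: tuple[float, float] = (0.02, 0.4)
    cord_center_range: tuple[float, float] = (-0.3, 0.3)
    cell_side: float = 0.02
    origin_exclusion: float = 0.05
    canal_r_max: float = 0.85
    canal_margin: float = 0.85
    bone_hu_threshold: float = 200.0
    min_points: int = 10
    min_votes: int = 5
    max_failed_fraction: float = 0.5

    def canal_parameter_grid(self) -> ParameterGrid:
        return canal_grid(self.canal_a_range, self.canal_b_range, self.cell_side)

    def cord_parameter_grid(self) -> ParameterGrid:
        return cord_grid(self.cord_axis_range, self.cord_center_range, self.cell_side)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        cfg = cls(**d)
        for name in ("bone_window", "soft_window", "canal_a_range",
                     "canal_b_range", "cord_axis_range", "cord_center_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class SliceFit:
    """Per-slice fit record: parameters in working units, center in pixels."""

    slice_index: int
    segment: str
    status: str
    canal: ThreeConvexityParams | None = None
    cord: EllipseParams | None = None
    canal_votes: int = 0
    cord_votes: int = 0
    center_px: tuple[float, float] | None = None


@dataclass
class SegmentationResult:
    """Canal/cord masks over the full volume plus per-slice fits and volumes."""

    canal_mask: np.ndarray  # (nslices, ny, nx) bool
    cord_mask: np.ndarray
    fits: list[SliceFit]
    segments: SegmentDefinition
    spacing: tuple[float, float, float]

    def segment_mask(self, segment: str, which: str = "cord") -> np.ndarray:
        mask = self.cord_mask if which == "cord" else self.canal_mask
        out = np.zeros_like(mask)
        sl = self.segments.slices(segment)
        out[sl.start:sl.stop] = mask[sl.start:sl.stop]
        return out

    def volume_ml(self, segment: str, which: str = "cord") -> float:
        sl = self.segments.slices(segment)
        mask = self.cord_mask if which == "cord" else self.canal_mask
        return compute_volume(list(mask[sl.start:sl.stop]), self.spacing)

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append({
                "slice": f.slice_index,
                "segment": f.segment,
                "status": f.status,
                "canal_a": f.canal.a if f.canal else np.nan,
                "canal_b": f.canal.b if f.canal else np.nan,
                "cord_a": f.cord.a if f.cord else np.nan,
                "cord_b": f.cord.b if f.cord else np.nan,
                "cord_c": f.cord.c if f.cord else np.nan,
                "cord_d": f.cord.d if f.cord else np.nan,
                "canal_votes": f.canal_votes,
                "cord_votes": f.cord_votes,
                "center_x_px": f.center_px[0] if f.center_px else np.nan,
                "center_y_px": f.center_px[1] if f.center_px else np.nan,
            })
        return pd.DataFrame(rows)


def partition_segments(volume: ImageVolume, occiput: int, c7: int,
                       d12: int) -> SegmentDefinition:
    """Validate the three user-marked planes against the volume extent."""
    n = volume.n_slices
    for name, idx in (("occiput", occiput), ("c7", c7), ("d12", d12)):
        if not 0 <= idx < n:
            raise ValueError(f"{name} slice {idx} outside volume of {n} slices")
    return SegmentDefinition(occiput_slice=occiput, c7_slice=c7, d12_slice=d12)


def _window_normalize(image: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (np.clip(image, lo, hi) - lo) / (hi - lo)


def estimate_canal_center(ct_slice: np.ndarray,
                          bone_hu_threshold: float = 200.0):
    """Estimate the canal center from the bone map of one slice.

    Takes the largest connected component of supra-threshold (bone) pixels
    and returns the centroid of the largest internal cavity of that
    component (the canal lumen).  Returns None when no bone or no cavity is
    found.
    """
    bone = np.asarray(ct_slice) > bone_hu_threshold
    if not bone.any():
        return None
    labels, n = ndimage.label(bone)
    largest = np.argmax(ndimage.sum_labels(bone, labels, range(1, n + 1))) + 1
    comp = labels == largest
    cavity = ndimage.binary_fill_holes(comp) & ~comp
    if not cavity.any():
        return None
    clab, cn = ndimage.label(cavity)
    big = np.argmax(ndimage.sum_labels(cavity, clab, range(1, cn + 1))) + 1
    cy, cx = ndimage.center_of_mass(clab == big)
    return (float(cx), float(cy))


def rasterize_mask(shape, frame: WorkingFrame, params) -> np.ndarray:
    """Rasterize the inside of a curve to a boolean mask of ``shape`` (ny, nx)."""
    ny, nx = shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    pix = np.stack([xs, ys], axis=-1).astype(float)
    return point_inside(frame.to_frame(pix), params)


def segment_slice(ct_slice: np.ndarray, prior_center, config: SegmentationConfig,
                  pixel_mm: float, slice_index: int = -1,
                  extra_points: np.ndarray | None = None) -> SliceFit:
    """Run canal and cord detection on one CT slice.

    ``prior_center`` (pixel x, y) seeds the working frame when the bone-map
    estimate is unavailable.  ``extra_points`` (working-frame coordinates)
    are appended to the edge sets — used by the robustness experiments to
    inject clutter.  Raises :class:`NoCurveFound` when detection fails.
    """
    center = estimate_canal_center(ct_slice, config.bone_hu_threshold)
    if center is None:
        center = prior_center
    if center is None:
        raise NoCurveFound(f"slice {slice_index}: no canal center estimate")

    scale_px = config.frame_scale_mm / pixel_mm
    frame = WorkingFrame(origin=center, scale=scale_px)

    # --- canal pass: bone window ---
    bone_img = _window_normalize(ct_slice, config.bone_window)
    edges = detect_edges(bone_img, sigma=config.canny_sigma,
                         low=config.canny_low, high=config.canny_high,
                         source_slice=slice_index)
    fpts = frame.to_frame(edges.points)
    if extra_points is not None and len(extra_points):
        fpts = np.vstack([fpts, np.asarray(extra_points, dtype=float)])
    r = np.hypot(fpts[:, 0], fpts[:, 1])
    keep = (r >= config.origin_exclusion) & (r <= config.canal_r_max)
    canal_pts = EdgePointSet(points=fpts[keep], source_slice=slice_index)
    canal, canal_votes = detect_canal(
        canal_pts, config.canal_parameter_grid(),
        min_points=config.min_points, min_votes=config.min_votes)

    # --- cord pass: narrow soft-tissue window, canal interior only ---
    soft_img = _window_normalize(ct_slice, config.soft_window)
    soft_edges = detect_edges(soft_img, sigma=config.canny_sigma,
                              low=config.canny_low, high=config.canny_high,
                              source_slice=slice_index)
    spts = frame.to_frame(soft_edges.points)
    if extra_points is not None and len(extra_points):
        spts = np.vstack([spts, np.asarray(extra_points, dtype=float)])
    shrunk = ThreeConvexityParams(a=canal.a * config.canal_margin, b=canal.b)
    inside = point_inside(spts, shrunk)
    cord_pts = EdgePointSet(points=spts[inside], source_slice=slice_index)
    cord, cord_votes = detect_cord(
        cord_pts, config.cord_parameter_grid(),
        min_points=config.min_points, min_votes=config.min_votes)

    return SliceFit(slice_index=slice_index,
                    segment="",
                    status="ok",
                    canal=canal, cord=cord,
                    canal_votes=canal_votes, cord_votes=cord_votes,
                    center_px=(float(center[0]), float(center[1])))


def segment_volume_run(ct: ImageVolume, segdef: SegmentDefinition,
                       config: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the per-slice chain over the cervical and dorsal segments.

    The canal-center prior propagates cranial→caudal.  Failed slices
    contribute empty masks; a segment with more than
    ``config.max_failed_fraction`` failed slices aborts the run.
    """
    if config is None:
        config = SegmentationConfig()
    if abs(ct.spacing[1] - ct.spacing[2]) > 1e-6:
        raise ValueError("anisotropic in-plane spacing is not supported")
    pixel_mm = ct.spacing[1]
    scale_px = config.frame_scale_mm / pixel_mm

    nz, ny, nx = ct.data.shape
    canal_mask = np.zeros((nz, ny, nx), dtype=bool)
    cord_mask = np.zeros((nz, ny, nx), dtype=bool)
    fits: list[SliceFit] = []
    failed = {CERVICAL: 0, DORSAL: 0}
    prior = None

    for k in segdef.analyzed:
        segment = segdef.segment_of(k)
        try:
            fit = segment_slice(ct.data[k], prior, config, pixel_mm,
                                slice_index=k)
            fit.segment = segment
            frame = WorkingFrame(origin=fit.center_px, scale=scale_px)
            cmask = rasterize_mask((ny, nx), frame, fit.canal)
            smask = rasterize_mask((ny, nx), frame, fit.cord) & cmask
            canal_mask[k] = cmask
            cord_mask[k] = smask
            prior = fit.center_px
        except NoCurveFound as err:
            logger.warning("slice %d (%s): %s", k, segment, err)
            fit = SliceFit(slice_index=k, segment=segment,
                           status=f"failed: {err}")
            failed[segment] += 1
        fits.append(fit)

    for segment in (CERVICAL, DORSAL):
        n = len(segdef.slices(segment))
        if n and failed[segment] / n > config.max_failed_fraction:
            raise SegmentationFailed(
                f"{failed[segment]}/{n} slices failed in the {segment} segment"
            )

    return SegmentationResult(canal_mask=canal_mask, cord_mask=cord_mask,
                              fits=fits, segments=segdef, spacing=ct.spacing)


def compute_volume(masks, spacing) -> float:
    """Volume in mL of a stack of 2D masks with the given voxel spacing (mm)."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        return 0.0
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all masks must share the same shape")
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    voxels = int(sum(int(m.sum()) for m in masks))
    return voxels * dz * dy * dx / 1000.0
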