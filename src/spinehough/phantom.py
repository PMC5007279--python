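"""Synthetic coregistered CT/PET phantoms with analytic ground truth.

The phantom emulates the inputs the pipeline expects from a whole-body
PET/CT scan, at desk scale:

* CT: a piecewise-constant HU map per axial slice — soft-tissue background,
  a high-attenuation vertebral ring whose inner boundary is exactly the
  three-convexity canal curve, an anterior vertebral-body disk, canal
  content (CSF-like) inside the ring, and a cord ellipse with a small
  configurable HU contrast over the canal content.  The ring thickness is
  modulated with angle so that only the *inner* (canal) boundary belongs to
  the three-convexity family — as in real vertebrae, where the outer bone
  contour is irregular.
* PET: a piecewise-constant uptake map (in true SUV units) convolved with a
  Gaussian point-spread function of the stated FWHM (4 mm by default, the
  resolution of the clinical scanners the method targets), plus seeded
  additive Gaussian noise.  A liver blob away from the spine provides the
  normalization reference.

Both grids are identical (perfect coregistration).  The truth record keeps
the generating parameters plus closed-form areas and volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .curves import (
    EllipseParams,
    ThreeConvexityParams,
    point_inside,
    sample_curve,
    three_convexity_area,
    three_convexity_radius,
)
from .metabolics import SubjectInfo
from .segmentation import CERVICAL, DORSAL, ImageVolume, SegmentDefinition

__all__ = [
    "PhantomTruth",
    "CohortMember",
    "default_truth",
    "generate_phantom",
    "default_subject",
    "default_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomTruth:
    """Generating parameters and ground truth of one phantom.

    Curve parameters are in working units; the frame scale converts them to
    mm (default 40 mm per unit).  Uptake values are true SUVs; the PET
    volume is derived from them through the subject's dose/weight ratio.
    """

    canal_a: float = 0.35
    canal_b: float = 0.15
    cord_a: float = 0.15
    cord_b: float = 0.13
    cord_c: float = 0.01
    cord_d: float = -0.01
    occiput_slice: int = 6
    c7_slice: int = 26
    d12_slice: int = 54
    canal_center_px: tuple[float, float] = (32.0, 32.0)
    frame_scale_mm: float = 40.0
    hu_soft: float = 40.0
    hu_canal: float = 15.0
    hu_bone: float = 700.0
    hu_liver: float = 60.0
    cord_contrast_hu: float = 30.0
    uptake_background: float = 0.5
    uptake_canal: float = 1.2
    uptake_cord_cervical: float = 1.7
    uptake_cord_dorsal: float = 1.5
    uptake_liver: float = 2.0
    ring_thickness: float = 0.12
    ring_thickness_mod: float = 0.05
    vertebral_body: bool = True
    body_center: tuple[float, float] = (0.0, -0.6)
    body_radius: float = 0.25
    liver_center_px: tuple[float, float] = (14.0, 50.0)
    liver_radius_mm: float = 8.0
    fwhm_mm: float = 4.0
    noise_suv: float = 0.05
    seed: int = 0

    def canal_params(self) -> ThreeConvexityParams:
        return ThreeConvexityParams(a=self.canal_a, b=self.canal_b)

    def cord_params(self) -> EllipseParams:
        return EllipseParams(a=self.cord_a, b=self.cord_b,
                             c=self.cord_c, d=self.cord_d)

    def segments(self) -> SegmentDefinition:
        return SegmentDefinition(self.occiput_slice, self.c7_slice,
                                 self.d12_slice)

    # --- analytic ground truth ---

    def canal_area_mm2(self) -> float:
        return three_convexity_area(self.canal_params()) * self.frame_scale_mm**2

    def cord_area_mm2(self) -> float:
        return float(np.pi * self.cord_a * self.cord_b) * self.frame_scale_mm**2

    def segment_length_mm(self, segment: str, slice_mm: float) -> float:
        seg = self.segments()
        return len(seg.slices(segment)) * slice_mm

    def cord_volume_ml(self, segment: str, slice_mm: float) -> float:
        return self.cord_area_mm2() * self.segment_length_mm(segment, slice_mm) / 1000.0

    def canal_volume_ml(self, segment: str, slice_mm: float) -> float:
        return self.canal_area_mm2() * self.segment_length_mm(segment, slice_mm) / 1000.0

    def cord_nsuv(self, segment: str) -> float:
        u = (self.uptake_cord_cervical if segment == CERVICAL
             else self.uptake_cord_dorsal)
        return u / self.uptake_liver

    def whole_cord_nsuv(self, slice_mm: float) -> float:
        vc = self.cord_volume_ml(CERVICAL, slice_mm)
        vd = self.cord_volume_ml(DORSAL, slice_mm)
        return (self.cord_nsuv(CERVICAL) * vc + self.cord_nsuv(DORSAL) * vd) / (vc + vd)

    def validate(self) -> None:
        """Check the cord ellipse lies strictly inside the canal lobe."""
        boundary = sample_curve(self.cord_params(), 360)
        if not np.all(point_inside(boundary, self.canal_params())):
            raise ValueError("cord ellipse is not strictly inside the canal curve")


def default_truth(**overrides) -> PhantomTruth:
    """The default phantom conditions; keyword overrides replace fields."""
    return replace(PhantomTruth(), **overrides)


def default_subject() -> SubjectInfo:
    """Reference subject: 70 kg, 5 MBq/kg FDG (350 MBq), 175 cm male."""
    return SubjectInfo(activity_mbq=350.0, weight_kg=70.0,
                       height_cm=175.0, sex="male")


def _paint_slice(truth: PhantomTruth, ny: int, nx: int, with_cord: bool):
    """Return (hu, uptake-template) 2D maps for one vertebral slice.

    The uptake template codes regions: 0 background, 1 canal content,
    2 cord (filled per-segment later), 3 bone.
    """
    cx, cy = truth.canal_center_px
    s = truth.frame_scale_mm  # pixels per unit at 1 mm in-plane spacing
    ys, xs = np.mgrid[0:ny, 0:nx]
    fx = (xs - cx) / s
    fy = (ys - cy) / s
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    r_canal = three_convexity_radius(theta, truth.canal_params())
    thickness = truth.ring_thickness + truth.ring_thickness_mod * np.sin(theta)

    hu = np.full((ny, nx), truth.hu_soft)
    region = np.zeros((ny, nx), dtype=np.int8)

    if truth.vertebral_body:
        bx, by = truth.body_center
        body = np.hypot(fx - bx, fy - by) <= truth.body_radius
        hu[body] = truth.hu_bone
        region[body] = 3
    ring = (r >= r_canal) & (r < r_canal + thickness)
    hu[ring] = truth.hu_bone
    region[ring] = 3
    interior = r < r_canal
    hu[interior] = truth.hu_canal
    region[interior] = 1
    if with_cord:
        cord = point_inside(np.stack([fx, fy], axis=-1), truth.cord_params())
        hu[cord] = truth.hu_canal + truth.cord_contrast_hu
        region[cord] = 2
    return hu, region


def generate_phantom(truth: PhantomTruth, shape=(60, 64, 64),
                     spacing=(3.0, 1.0, 1.0),
                     subject: SubjectInfo | None = None):
    """Build coregistered CT and PET volumes from a truth record.

    Returns ``(ct, pet, truth)``.  The PET volume holds activity
    concentration in kBq/mL derived from the true SUV map through the
    subject's dose/weight ratio, blurred with the PSF and with seeded
    Gaussian noise added.
    """
    truth.validate()
    nz, ny, nx = shape
    if nz < 10 or ny < 32 or nx < 32:
        raise ValueError(f"phantom shape must be at least 10x32x32, got {shape}")
    seg = truth.segments()
    if seg.d12_slice >= nz:
        raise ValueError("d12 plane outside the volume")
    if subject is None:
        subject = default_subject()
    if abs(spacing[1] - spacing[2]) > 1e-9:
        raise ValueError("phantom requires isotropic in-plane spacing")
    if abs(spacing[1] - 1.0) > 1e-9:
        # frame_scale_mm is defined in mm; pixel painting assumes 1 mm pixels
        raise ValueError("phantom painting assumes 1 mm in-plane spacing")

    ct = np.full((nz, ny, nx), truth.hu_soft)
    suv = np.full((nz, ny, nx), truth.uptake_background)

    hu_cord, region_cord = _paint_slice(truth, ny, nx, with_cord=True)
    hu_plain, region_plain = _paint_slice(truth, ny, nx, with_cord=False)

    for k in range(seg.occiput_slice, nz):
        with_cord = k <= seg.d12_slice
        hu, region = (hu_cord, region_cord) if with_cord else (hu_plain, region_plain)
        ct[k] = hu
        sl = suv[k]
        sl[region == 1] = truth.uptake_canal
        if with_cord:
            u = (truth.uptake_cord_cervical if k < seg.c7_slice
                 else truth.uptake_cord_dorsal)
            sl[region == 2] = u

    # liver blob, painted only over soft tissue
    lx, ly = truth.liver_center_px
    ys, xs = np.mgrid[0:ny, 0:nx]
    liver2d = np.hypot((xs - lx) * spacing[2], (ys - ly) * spacing[1]) \
        <= truth.liver_radius_mm
    z_lo = max(0, seg.d12_slice - 6)
    z_hi = min(nz, seg.d12_slice + 5)
    for k in range(z_lo, z_hi):
        paint = liver2d & (ct[k] == truth.hu_soft)
        ct[k][paint] = truth.hu_liver
        suv[k][paint] = truth.uptake_liver

    if truth.fwhm_mm > 0:
        sigma_vox = [truth.fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
        suv = ndimage.gaussian_filter(suv, sigma=sigma_vox)
    if truth.noise_suv > 0:
        rng = np.random.default_rng(truth.seed)
        suv = suv + rng.normal(0.0, truth.noise_suv, size=suv.shape)

    dose_per_gram = subject.activity_mbq * 1000.0 / (subject.weight_kg * 1000.0)
    pet = suv * dose_per_gram  # kBq/mL

    return (ImageVolume(data=ct, spacing=spacing, modality="CT"),
            ImageVolume(data=pet, spacing=spacing, modality="PET"),
            truth)


@dataclass(frozen=True)
class CohortMember:
    """One simulated subject: phantom truth plus injection metadata."""

    subject_id: str
    group: str  # "case" (ALS-like) or "control"
    truth: PhantomTruth
    subject: SubjectInfo
    sc_nsuv: float  # whole-cord NSUV target drawn for this subject


# printed group-level conditions the cohort simulator reproduces
CASE_SC_NSUV = (0.82, 0.28)      # mean, SD — patients
CONTROL_SC_NSUV = (0.70, 0.14)   # mean, SD — controls
CASE_SEGMENT_NSUV = (0.99, 0.72)     # cervical, dorsal — patients
CONTROL_SEGMENT_NSUV = (0.85, 0.62)  # cervical, dorsal — controls
_NSUV_FLOOR = 0.05


def _truncated_normal(rng, mean, sd, n, floor=_NSUV_FLOOR):
    out = rng.normal(mean, sd, size=n)
    while np.any(out < floor):
        bad = out < floor
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def default_cohort(n_cases: int, n_controls: int, seed: int = 0,
                   slice_mm: float = 3.0) -> list[CohortMember]:
    """Simulate a cohort whose group NSUV distributions match the study's.

    Cases draw the whole-cord NSUV from Normal(0.82, 0.28) and controls from
    Normal(0.70, 0.14), truncated at 0.05.  The cervical/dorsal split echoes
    the printed segment means (0.99/0.72 for cases, 0.85/0.62 for controls),
    rescaled so the volume-weighted mean reproduces each subject's draw
    exactly.  Each member carries a full phantom truth record whose cord
    uptake realizes those NSUVs; call :func:`generate_phantom` to materialize
    the volumes.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    base = PhantomTruth()
    vc = base.cord_volume_ml(CERVICAL, slice_mm)
    vd = base.cord_volume_ml(DORSAL, slice_mm)

    members: list[CohortMember] = []
    specs = [("case", n_cases, CASE_SC_NSUV, CASE_SEGMENT_NSUV),
             ("control", n_controls, CONTROL_SC_NSUV, CONTROL_SEGMENT_NSUV)]
    for group, n, (mean, sd), (seg_c, seg_d) in specs:
        draws = _truncated_normal(rng, mean, sd, n)
        wbar = (seg_c * vc + seg_d * vd) / (vc + vd)
        for i, sc in enumerate(draws):
            c_nsuv = sc * seg_c / wbar
            d_nsuv = sc * seg_d / wbar
            weight = float(np.clip(rng.normal(70.0, 10.0), 45.0, 110.0))
            height = float(np.clip(rng.normal(170.0, 9.0), 152.4, 200.0))
            sex = "male" if rng.random() < 2.0 / 3.0 else "female"
            member_seed = int(rng.integers(0, 2**31 - 1))
            truth = replace(
                base,
                uptake_cord_cervical=float(c_nsuv * base.uptake_liver),
                uptake_cord_dorsal=float(d_nsuv * base.uptake_liver),
                seed=member_seed,
            )
            subject = SubjectInfo(activity_mbq=5.0 * weight, weight_kg=weight,
                                  height_cm=height, sex=sex)
            members.append(CohortMember(
                subject_id=f"{group}-{i:03d}", group=group, truth=truth,
                subject=subject, sc_nsuv=float(sc)))
    return members
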