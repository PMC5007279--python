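"""SUV extraction under the masks, liver normalization, whole-cord NSUV.

SUV is the standard body-weight-normalized uptake,

    SUV = C / (A / W),

with ``C`` the activity concentration (kBq/mL), ``A`` the injected activity
(kBq) and ``W`` the body weight in grams (tissue density taken as 1 g/mL),
so a perfectly uniform distribution of the dose gives SUV = 1 everywhere.

Segment SUVs are divided by the mean liver SUV (NSUV), removing scanner
sensitivity differences, and the whole-cord value is the volume-weighted
mean of the cervical and dorsal segment NSUVs:

    SC_NSUV = (C_NSUV·V_cerv + D_NSUV·V_dors) / (V_cerv + V_dors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CERVICAL, DORSAL, ImageVolume, SegmentationResult

__all__ = [
    "SubjectInfo",
    "UptakeReport",
    "F18_HALF_LIFE_MIN",
    "compute_suv",
    "mean_suv_in_mask",
    "normalize_to_liver",
    "whole_cord_nsuv",
    "ideal_body_weight",
    "decay_correction_factor",
    "spherical_roi_mask",
    "liver_reference_suv",
    "quantify",
]

F18_HALF_LIFE_MIN = 109.77  # 18F physical half-life, minutes


@dataclass(frozen=True)
class SubjectInfo:
    """Injection and anthropometric data needed for SUV computation.

    ``decay_corrected`` states whether the PET voxel values are already
    decay-corrected to injection time (the standard scanner behaviour); when
    False, ``uptake_time_min`` is used to correct them explicitly with the
    18F half-life.
    """

    activity_mbq: float
    weight_kg: float
    height_cm: float | None = None
    sex: str | None = None
    decay_corrected: bool = True
    uptake_time_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.activity_mbq > 0:
            raise ValueError(f"injected activity must be > 0, got {self.activity_mbq}")
        if not self.weight_kg > 0:
            raise ValueError(f"body weight must be > 0, got {self.weight_kg}")


def decay_correction_factor(minutes: float) -> float:
    """Factor bringing an activity measured ``minutes`` post-injection back
    to injection time: ``2^(t/T_half)`` with the 18F half-life."""
    return float(2.0 ** (minutes / F18_HALF_LIFE_MIN))


def compute_suv(concentration, subject: SubjectInfo):
    """SUV of activity concentration(s) in kBq/mL; dimensionless.

    ``SUV = C·W[g] / A[kBq]``; optionally decay-corrects raw values first.
    """
    conc = np.asarray(concentration, dtype=float)
    if not subject.decay_corrected:
        conc = conc * decay_correction_factor(subject.uptake_time_min)
    suv = conc * (subject.weight_kg * 1000.0) / (subject.activity_mbq * 1000.0)
    return suv if suv.ndim else float(suv)


def mean_suv_in_mask(pet: ImageVolume, masks, subject: SubjectInfo) -> float:
    """Mean SUV over all mask-true voxels of the coregistered PET volume."""
    mask = np.asarray(masks, dtype=bool)
    if mask.shape != pet.data.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match PET {pet.data.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no voxels to average")
    return float(np.mean(compute_suv(pet.data[mask], subject)))


def normalize_to_liver(mean_suv: float, liver_suv: float) -> float:
    """NSUV = mean SUV divided by the mean liver SUV."""
    if not liver_suv > 0:
        raise ValueError(f"liver SUV must be > 0, got {liver_suv}")
    return float(mean_suv) / float(liver_suv)


def whole_cord_nsuv(c_nsuv: float, d_nsuv: float, cervical_vol: float,
                    dorsal_vol: float) -> float:
    """Volume-weighted whole-cord NSUV (convex combination of the segments)."""
    if cervical_vol < 0 or dorsal_vol < 0:
        raise ValueError("segment volumes must be >= 0")
    total = cervical_vol + dorsal_vol
    if total <= 0:
        raise ValueError("at least one segment volume must be positive")
    return (c_nsuv * cervical_vol + d_nsuv * dorsal_vol) / total


def ideal_body_weight(sex: str, height_cm: float) -> float:
    """Ideal body weight (kg) by the Robinson formula.

    Men: 52 kg + 1.9 kg per inch over 5 ft; women: 49 kg + 1.7 kg per inch.
    Undefined below 152.4 cm (60 in).
    """
    height_in = height_cm / 2.54
    if height_in < 60.0:
        raise ValueError(
            f"ideal body weight undefined below 152.4 cm, got {height_cm} cm"
        )
    s = sex.strip().lower()
    if s in ("m", "male", "man"):
        return 52.0 + 1.9 * (height_in - 60.0)
    if s in ("f", "female", "woman"):
        return 49.0 + 1.7 * (height_in - 60.0)
    raise ValueError(f"sex must be male or female, got {sex!r}")


def spherical_roi_mask(shape, spacing, center_mm, diameter_mm: float = 30.0
                       ) -> np.ndarray:
    """Boolean mask of a sphere given in mm coordinates on the volume grid.

    ``center_mm`` is (z, y, x) in mm measured from the voxel-(0,0,0) center.
    """
    dz, dy, dx = spacing
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    cz, cy, cx = center_mm
    d2 = ((zz * dz - cz) ** 2 + (yy * dy - cy) ** 2 + (xx * dx - cx) ** 2)
    return d2 <= (diameter_mm / 2.0) ** 2


def liver_reference_suv(pet: ImageVolume, subject: SubjectInfo,
                        liver_mask: np.ndarray | None = None,
                        center_mm=None, diameter_mm: float = 30.0) -> float:
    """Mean SUV of the liver reference region.

    Either a precomputed ``liver_mask`` or a spherical ROI (default 3 cm
    diameter) at ``center_mm`` must be supplied.
    """
    if liver_mask is None:
        if center_mm is None:
            raise ValueError("supply either liver_mask or center_mm")
        liver_mask = spherical_roi_mask(pet.data.shape, pet.spacing,
                                        center_mm, diameter_mm)
    return mean_suv_in_mask(pet, liver_mask, subject)


@dataclass
class UptakeReport:
    """Per-segment uptake summary of one subject."""

    liver_suv: float
    cervical_cord_nsuv: float
    dorsal_cord_nsuv: float
    cervical_canal_nsuv: float
    dorsal_canal_nsuv: float
    cervical_cord_volume_ml: float
    dorsal_cord_volume_ml: float
    cervical_canal_volume_ml: float
    dorsal_canal_volume_ml: float
    whole_cord_nsuv: float
    subject_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject_id, "segment": CERVICAL,
             "canal_nsuv": self.cervical_canal_nsuv,
             "cord_nsuv": self.cervical_cord_nsuv,
             "canal_volume_ml": self.cervical_canal_volume_ml,
             "cord_volume_ml": self.cervical_cord_volume_ml,
             "liver_suv": self.liver_suv,
             "whole_cord_nsuv": self.whole_cord_nsuv},
            {"subject": self.subject_id, "segment": DORSAL,
             "canal_nsuv": self.dorsal_canal_nsuv,
             "cord_nsuv": self.dorsal_cord_nsuv,
             "canal_volume_ml": self.dorsal_canal_volume_ml,
             "cord_volume_ml": self.dorsal_cord_volume_ml,
             "liver_suv": self.liver_suv,
             "whole_cord_nsuv": self.whole_cord_nsuv},
        ]
        return pd.DataFrame(rows)


def quantify(pet: ImageVolume, seg: SegmentationResult, subject: SubjectInfo,
             liver_mask: np.ndarray | None = None, liver_center_mm=None,
             liver_diameter_mm: float = 30.0, subject_id: str = ""
             ) -> UptakeReport:
    """Extract PET uptake under the segmentation masks and build the report."""
    if pet.data.shape != seg.canal_mask.shape:
        raise ValueError("PET volume and masks are not on the same grid")
    liver = liver_reference_suv(pet, subject, liver_mask=liver_mask,
                                center_mm=liver_center_mm,
                                diameter_mm=liver_diameter_mm)
    vals = {}
    for segment in (CERVICAL, DORSAL):
        for which in ("cord", "canal"):
            mask = seg.segment_mask(segment, which)
            vals[(segment, which)] = normalize_to_liver(
                mean_suv_in_mask(pet, mask, subject), liver)
    v_cerv = seg.volume_ml(CERVICAL, "cord")
    v_dors = seg.volume_ml(DORSAL, "cord")
    return UptakeReport(
        liver_suv=liver,
        cervical_cord_nsuv=vals[(CERVICAL, "cord")],
        dorsal_cord_nsuv=vals[(DORSAL, "cord")],
        cervical_canal_nsuv=vals[(CERVICAL, "canal")],
        dorsal_canal_nsuv=vals[(DORSAL, "canal")],
        cervical_cord_volume_ml=v_cerv,
        dorsal_cord_volume_ml=v_dors,
        cervical_canal_volume_ml=seg.volume_ml(CERVICAL, "canal"),
        dorsal_canal_volume_ml=seg.volume_ml(DORSAL, "canal"),
        whole_cord_nsuv=whole_cord_nsuv(
            vals[(CERVICAL, "cord")], vals[(DORSAL, "cord")], v_cerv, v_dors),
        subject_id=subject_id,
    )
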