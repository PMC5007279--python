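"""Volume I/O (NIfTI and DICOM series), run configuration, pipeline driver.

Volumes are normalized on read to the package convention: array axes
(slice, row, column) with slice index 0 most cranial, spacing in mm per
axis.  NIfTI files are reoriented through their affine; DICOM series are
sorted by table position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .metabolics import SubjectInfo, quantify
from .segmentation import (
    ImageVolume,
    SegmentationConfig,
    partition_segments,
    segment_volume_run,
)

logger = logging.getLogger("spinehough")

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "run_pipeline",
]


def _canonical_from_nifti(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    """RAS-canonicalize and convert to (slice, row, col), cranial first."""
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # canonical axes are (R, A, S); slice axis is S with superior = high index
    vol = np.transpose(data, (2, 1, 0))[::-1].copy()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return vol, spacing


def read_volume(path, modality: str = "CT") -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory.

    DICOM rescale slope/intercept are applied; slice order is normalized to
    cranial→caudal regardless of how the file or series is stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        return _read_dicom_series(path, modality)
    try:
        img = nib.load(str(path))
    except Exception as err:  # unreadable / wrong format
        raise ValueError(f"cannot read volume {path}: {err}") from err
    vol, spacing = _canonical_from_nifti(img)
    return ImageVolume(data=vol, spacing=spacing, modality=modality)


def _read_dicom_series(directory: Path, modality: str) -> ImageVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append((f, ds))
    if not datasets:
        raise ValueError(f"no readable DICOM images in {directory}")
    uids = {ds.SeriesInstanceUID for _, ds in datasets}
    if len(uids) != 1:
        offender = next(f for f, ds in datasets
                        if ds.SeriesInstanceUID != datasets[0][1].SeriesInstanceUID)
        raise ValueError(
            f"mixed DICOM series in {directory}: {offender.name} belongs to a "
            f"different series"
        )
    # sort cranial→caudal: superior = larger patient z
    datasets.sort(key=lambda t: -float(t[1].ImagePositionPatient[2]))
    slices = []
    for _, ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    first = datasets[0][1]
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        z = [float(ds.ImagePositionPatient[2]) for _, ds in datasets]
        dz = float(abs(np.diff(z).mean()))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    vol = np.stack(slices)
    mod = str(getattr(first, "Modality", modality)) or modality
    return ImageVolume(data=vol, spacing=(dz, row_mm, col_mm), modality=mod)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI, invertible by :func:`read_volume`."""
    dz, dy, dx = volume.spacing
    data = np.transpose(volume.data[::-1], (2, 1, 0))
    affine = np.diag([dx, dy, dz, 1.0])
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data), affine), str(path))


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``liver_center_mm`` locates the spherical liver reference ROI in volume
    mm coordinates (z, y, x); alternatively ``liver_mask_path`` points to a
    mask volume on the same grid.
    """

    ct_path: str
    pet_path: str
    occiput_slice: int
    c7_slice: int
    d12_slice: int
    output_dir: str
    activity_mbq: float
    weight_kg: float
    height_cm: float | None = None
    sex: str | None = None
    liver_center_mm: tuple[float, float, float] | None = None
    liver_diameter_mm: float = 30.0
    liver_mask_path: str | None = None
    subject_id: str = ""
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        seg = raw.pop("segmentation", None)
        cfg = cls(**raw)
        if seg is not None:
            cfg.segmentation = SegmentationConfig.from_dict(seg)
        if cfg.liver_center_mm is not None:
            cfg.liver_center_mm = tuple(cfg.liver_center_mm)
        return cfg

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    def validate(self) -> None:
        for name in ("ct_path", "pet_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.liver_mask_path is not None \
                and not Path(self.liver_mask_path).exists():
            raise FileNotFoundError(
                f"liver_mask_path does not exist: {self.liver_mask_path}")
        if self.liver_mask_path is None and self.liver_center_mm is None:
            raise ValueError("config must give liver_center_mm or liver_mask_path")


def run_pipeline(config: RunConfig) -> "UptakeReportFiles":
    """Execute segmentation → quantification → report for one subject.

    Writes, under ``config.output_dir``: canal/cord masks (NIfTI), the
    per-slice fit table, and the uptake report (both tab-delimited).
    Deterministic: identical inputs produce byte-identical outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        ct = read_volume(config.ct_path, modality="CT")
        pet = read_volume(config.pet_path, modality="PET")
        if ct.data.shape != pet.data.shape:
            raise ValueError("CT and PET are not on the same grid")
        segdef = partition_segments(ct, config.occiput_slice,
                                    config.c7_slice, config.d12_slice)
        logger.info("segmenting %d slices", len(segdef.analyzed))
        seg = segment_volume_run(ct, segdef, config.segmentation)

        subject = SubjectInfo(activity_mbq=config.activity_mbq,
                              weight_kg=config.weight_kg,
                              height_cm=config.height_cm, sex=config.sex)
        liver_mask = None
        if config.liver_mask_path is not None:
            liver_mask = read_volume(config.liver_mask_path).data.astype(bool)
        report = quantify(pet, seg, subject,
                          liver_mask=liver_mask,
                          liver_center_mm=config.liver_center_mm,
                          liver_diameter_mm=config.liver_diameter_mm,
                          subject_id=config.subject_id)

        write_volume(ImageVolume(seg.canal_mask.astype(np.uint8), ct.spacing),
                     out / "canal_mask.nii")
        write_volume(ImageVolume(seg.cord_mask.astype(np.uint8), ct.spacing),
                     out / "cord_mask.nii")
        seg.fit_table().to_csv(out / "fits.tsv", sep="\t", index=False)
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        logger.info("whole-cord NSUV %.4f", report.whole_cord_nsuv)
        return UptakeReportFiles(report=report, segmentation=seg,
                                 output_dir=out)
    finally:
        logger.removeHandler(handler)
        handler.close()


@dataclass
class UptakeReportFiles:
    report: object
    segmentation: object
    output_dir: Path
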