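"""Recovery and closure experiments on phantoms.

Shared by the test suite and the results-reproduction script: parameter
recovery rates over the analyzed slices (optionally with injected edge
clutter), and volume closure of a constant-cross-section phantom against
the analytic areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hough import NoCurveFound
from .phantom import PhantomTruth
from .segmentation import (
    ImageVolume,
    SegmentationConfig,
    segment_slice,
)

__all__ = ["RecoveryRates", "recovery_rates", "volume_closure_error"]


@dataclass(frozen=True)
class RecoveryRates:
    """Fraction of analyzed slices recovered within one accumulator cell."""

    canal_pct: float
    cord_pct: float
    n_slices: int
    n_failed: int


def _within_one_cell(estimate, truth, side) -> bool:
    return all(abs(e - t) <= side + 1e-12 for e, t in zip(estimate, truth))


def recovery_rates(ct: ImageVolume, truth: PhantomTruth,
                   config: SegmentationConfig | None = None,
                   clutter_fraction: float = 0.0,
                   seed: int = 0) -> RecoveryRates:
    """Per-slice canal (a, b) and cord (a, b, c, d) recovery rates.

    A slice counts as recovered when every fitted parameter lies within one
    cell side of the generating value.  ``clutter_fraction`` adds that
    fraction of uniformly scattered bogus edge points (working-frame square
    of half-width 0.6) to each slice's edge sets before voting.
    """
    if config is None:
        config = SegmentationConfig()
    side = config.cell_side
    seg = truth.segments()
    canal_truth = (truth.canal_a, truth.canal_b)
    cord_truth = (truth.cord_a, truth.cord_b, truth.cord_c, truth.cord_d)
    rng = np.random.default_rng(seed)
    pixel_mm = ct.spacing[1]

    canal_ok = cord_ok = failed = 0
    n = 0
    prior = truth.canal_center_px
    for k in seg.analyzed:
        n += 1
        extra = None
        if clutter_fraction > 0:
            # scale clutter count to a typical slice's edge budget
            n_clutter = max(1, int(round(clutter_fraction * 100)))
            extra = rng.uniform(-0.6, 0.6, size=(n_clutter, 2))
        try:
            fit = segment_slice(ct.data[k], prior, config, pixel_mm,
                                slice_index=k, extra_points=extra)
        except NoCurveFound:
            failed += 1
            continue
        prior = fit.center_px
        if _within_one_cell((fit.canal.a, fit.canal.b), canal_truth, side):
            canal_ok += 1
        if _within_one_cell((fit.cord.a, fit.cord.b, fit.cord.c, fit.cord.d),
                            cord_truth, side):
            cord_ok += 1
    return RecoveryRates(canal_pct=100.0 * canal_ok / n,
                         cord_pct=100.0 * cord_ok / n,
                         n_slices=n, n_failed=failed)


def volume_closure_error(truth: PhantomTruth, shape=(60, 64, 64),
                         spacing=(3.0, 1.0, 1.0)) -> dict:
    """Rasterized-truth volume vs analytic area × length, in percent.

    Builds the masks directly from the generating parameters (no detection)
    and compares the voxel-counted volume with the closed-form area times
    the analyzed length — a closure check of rasterization plus volume
    arithmetic.
    """
    from .curves import WorkingFrame
    from .segmentation import compute_volume, rasterize_mask

    ny, nx = shape[1], shape[2]
    scale_px = truth.frame_scale_mm / spacing[2]
    frame = WorkingFrame(origin=truth.canal_center_px, scale=scale_px)
    canal2d = rasterize_mask((ny, nx), frame, truth.canal_params())
    cord2d = rasterize_mask((ny, nx), frame, truth.cord_params()) & canal2d

    seg = truth.segments()
    n_slices = len(seg.analyzed)
    length_mm = n_slices * spacing[0]
    out = {}
    for name, mask2d, area in (
        ("canal", canal2d, truth.canal_area_mm2()),
        ("cord", cord2d, truth.cord_area_mm2()),
    ):
        measured = compute_volume([mask2d] * n_slices, spacing)
        analytic = area * length_mm / 1000.0
        out[name] = {
            "measured_ml": measured,
            "analytic_ml": analytic,
            "error_pct": 100.0 * abs(measured - analytic) / analytic,
        }
    return out
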