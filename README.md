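# spinehough

Operator-independent extraction of the **spinal canal** and **spinal cord**
from whole-body FDG-PET/CT, with liver-normalized standardized-uptake-value
(NSUV) quantification per anatomical segment.

The spinal cord is hard to analyse with nuclear-medicine methods: it is
thin, it is not surrounded by bone on every axial slice, and manual ROI
placement is slow and observer-dependent. This package implements a fully
deterministic pattern-recognition pipeline that needs only three
user-marked axial planes (occipital skull border, caudal C7, caudal D12)
and is aimed at researchers quantifying cord metabolism — e.g. in motor
neuron disease, myelitis, or post-traumatic states — from routine
low-dose-CT + PET acquisitions.

## Method

Curves are found per axial CT slice with a generalized Hough transform:

1. **Canny** edge detection extracts intensity discontinuities.
2. Each edge point is mapped to its **Hough hypersurface** — the set of
   curve parameters whose curve passes through that point.
3. The parameter space is discretized into cells of side **0.02**
   (squares for the canal family, hypercubes for the cord family).
4. An **accumulator** counts, per cell, the Hough hypersurfaces crossing it.
5. The recognized curve sits at the **accumulator maximum**.

The spinal canal is matched by the two-parameter family of curves with
three convexities

    C_{a,b}:  (x² + y²)³ = (a(x² + y²) − b(x³ − 3xy²))²,

whose bounded lobe has polar form `r(θ) = a / (1 + b·cos 3θ)` (|b| < 1),
and the cord by the four-parameter ellipse family

    E_{a,b,c,d}:  b²(x − c)² + a²(y − d)² − a²b² = 0.

Both curves are rasterized to binary masks (cord ⊆ canal), the masks are
multiplied against the coregistered PET volume, and mean SUVs are
normalized to the mean liver SUV. The whole-cord value is the
volume-weighted combination of the cervical and dorsal segments:

    SC_NSUV = (C_NSUV·V_cerv + D_NSUV·V_dors) / (V_cerv + V_dors).

A synthetic phantom module generates coregistered CT/PET volumes with
analytic ground truth (vertebral ring, canal lumen with three-convexity
cross-section, elliptical cord, 4 mm-FWHM PET blur) and a cohort simulator
draws group NSUV distributions at published group-level means and SDs.

## Worked example

```python
from spinehough.phantom import default_truth, generate_phantom, default_subject
from spinehough.segmentation import segment_volume_run
from spinehough.metabolics import quantify

truth = default_truth(noise_suv=0.0)          # noise-free phantom
ct, pet, truth = generate_phantom(truth)      # 60 axial slices, 3x1x1 mm
seg = segment_volume_run(ct, truth.segments())

rep = quantify(pet, seg, default_subject(),
               liver_center_mm=(159.0, 50.0, 14.0), liver_diameter_mm=10.0)
print(f"cervical cord: {rep.cervical_cord_volume_ml:.2f} mL, "
      f"NSUV {rep.cervical_cord_nsuv:.3f}")
print(f"dorsal cord:   {rep.dorsal_cord_volume_ml:.2f} mL, "
      f"NSUV {rep.dorsal_cord_nsuv:.3f}")
print(f"whole-cord NSUV: {rep.whole_cord_nsuv:.4f}")
```

prints

```
cervical cord: 5.82 mL, NSUV 0.794
dorsal cord:   8.44 mL, NSUV 0.721
whole-cord NSUV: 0.7510
```

The cervical cord volume is within 1 % of the analytic truth (5.88 mL) and
the whole-cord NSUV within 5 % of the generating value (0.7908); the
shortfall is the expected partial-volume loss of a ~1 cm cord at 4 mm PSF
FWHM. Every analyzed slice recovers the canal (a, b) and cord (a, b, c, d)
parameters within one 0.02 accumulator cell of truth.

The same pipeline is available from the shell:

```
spinehough phantom --out demo --seed 0
spinehough segment --ct demo/ct.nii --occiput 6 --c7 26 --d12 54 --out seg
spinehough cohort --cases 30 --controls 30 --seed 0
```

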