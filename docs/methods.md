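# Methods

## The recognition model

Each axial CT slice is searched for two closed curves: the spinal canal,
modeled by the two-parameter sextic with three convexities

C_{a,b}: (x²+y²)³ = (a(x²+y²) − b(x³−3xy²))²,

and the spinal cord, modeled by the four-parameter axis-aligned ellipse
E_{a,b,c,d}: b²(x−c)² + a²(y−d)² = a²b². For |b| < 1 the bounded lobe of
C_{a,b} has the closed polar form r(θ) = a/(1 + b·cos 3θ) about its center,
which exposes its exact three-fold symmetry; |b| ≥ 1 makes the radius
diverge and is rejected at construction. The origin is an algebraic double
root of the implicit equation (both sides vanish), so edge points within a
small exclusion radius (default 0.05 working units) of the frame origin are
discarded before voting.

Detection is vote-based, not regression: every Canny edge point votes for
all parameter cells whose curve passes through it, and the fitted curve is
the accumulator maximum. This makes the chain fully deterministic — there
is no initialization, no iteration, and no randomness anywhere from CT to
report, which the test suite checks at bit level.

### Working frame

C_{a,b} carries no translation parameters, so translation must be resolved
outside the parameter space. Each slice is analysed in a working frame
whose origin is a canal-center estimate and whose scale (default 40 mm per
working unit) puts the expected canal radius at ≈ 0.2–0.6 working units;
the 0.02 cell side of the discretized parameter space is then a 3–10 %
relative resolution on the canal scale. The center estimate is the
centroid of the largest internal cavity of the largest connected
high-attenuation (> 200 HU) component — the canal lumen surrounded by the
vertebra — falling back to the previous slice's center where the bone map
is uninformative (e.g. between vertebral bodies).

### Voting rule and tolerance

"The number of Hough transforms passing through a cell" is realized as a
residual band around the curve of each cell's *center* parameters. The
tolerance is the first-order bound on the constraint change when each
parameter moves by half a cell side, so a point exactly on a curve whose
parameters lie anywhere inside a cell is guaranteed (exactly for the canal
family, to first order for the ellipse) to vote for that cell:

* canal: an edge point at polar coordinates (r, θ) lies on C_{a,b} iff
  a = r + b·r·cos 3θ — *linear* in (a, b). Membership:
  |r(1 + b·cos 3θ) − a| ≤ (s/2)(1 + r|cos 3θ|), s = 0.02. This equals the
  exact line-cell intersection test.
* ellipse: F = b²(x−c)² + a²(y−d)² − a²b²; membership |F| ≤ (s/2)·Σ|∂F/∂p|
  over the four parameters, evaluated at the cell center.

The vectorized accumulator is checked in the tests against an independent
scalar (point × cell) loop for exact count equality.

### Peak search and tie-breaking

The peak is the maximal cell. Because the canal family's Hough lines in
(a, b) have slope r·cos 3θ with |r·cos 3θ| < 1 at anatomical scales, a
curve sampled exactly on cell-center parameters produces a small plateau of
maximal cells symmetric about the truth (both b-neighbors are crossed by
every line that crosses the true cell). Ties are therefore broken in two
deterministic stages: the tied cell nearest the centroid of the tied set
wins (the plateau center is the correct representative), and any remaining
tie falls to the lowest lexicographic cell index. For a two-cell tie the
two cells are always equidistant from their centroid, so the rule reduces
to plain lexicographic order there.

### Per-slice chain and segment bookkeeping

Bone-windowed (clamp to [−100, 1500] HU) Canny (σ = 1 px, hysteresis
thresholds 0.1/0.3 on the gradient of the window-normalized image) feeds
canal voting over the default grid a ∈ [0.1, 0.7], b ∈ [−0.5, 0.5]. The
cord pass re-runs Canny under a narrow soft-tissue window ([−50, 150] HU),
because the cord–CSF contrast is a few tens of HU and would vanish against
bone-scale gradients; its edge points are filtered to the interior of the
detected canal *shrunk to 85 %* so that canal-boundary pixels cannot
contaminate the ellipse vote, then voted over semi-axes ∈ [0.02, 0.4] and
centers ∈ [−0.3, 0.3]. All ranges, windows and thresholds are
configuration, not constants; the thresholds were calibrated once on the
synthetic phantom and are stated here as package defaults.

Slices are processed cranial→caudal with the fitted center propagated as
the next prior. The cervical segment is the half-open range [occiput, C7)
and the dorsal segment the closed range [C7, D12]; slices caudal to D12
hold no cord and are excluded. A failed slice contributes empty masks and
a logged record; a segment aborts only when more than half its slices
fail. Masks are rasterized by the strict inside test at pixel centers, the
cord mask is intersected with the canal mask, and volumes are voxel count
× voxel volume.

## SUV, NSUV and body weight

SUV = C·W/A with C the activity concentration (kBq/mL), A the injected
activity (kBq) and W the body weight in grams (density 1 g/mL), so a
uniform distribution of the dose gives SUV 1 everywhere. PET voxel values
are assumed decay-corrected to injection time by the scanner (standard
behaviour); a flag applies an explicit 18F correction (half-life
109.77 min) for raw data. Actual body weight enters the SUV; the Robinson
ideal body weight (men 52 kg + 1.9 kg/in over 5 ft; women 49 kg +
1.7 kg/in; undefined below 60 in) is computed as a reported covariate
only. The liver reference is the mean SUV in a user-supplied mask or a
spherical ROI (default 3 cm diameter) at a user-given coordinate; NSUV is
the ratio to that reference, which makes every NSUV exactly invariant
under a global scanner-sensitivity rescaling. The whole-cord NSUV is the
volume-weighted mean of the cervical and dorsal cord NSUVs and is by
construction a convex combination of the two.

## The phantom: what it emulates and what it does not

The phantom paints, per slice, a soft-tissue background (40 HU), a
high-attenuation ring (700 HU) whose **inner** boundary is exactly C_{a,b},
canal content at 15 HU, a cord ellipse at +30 HU over the canal content,
and an anterior vertebral-body disk. The ring thickness is modulated with
angle (0.12 ± 0.05 working units) so the outer bone contour does *not*
belong to the three-convexity family — as in real vertebrae — and cannot
compete with the canal at the accumulator maximum. PET is the
piecewise-constant true-SUV map (background 0.5, canal content 1.2, cord
1.7 cervical / 1.5 dorsal, liver 2.0) scaled by dose/weight, convolved
with an isotropic Gaussian PSF of 4 mm FWHM — the clinical scanner
resolution the method targets — plus seeded additive Gaussian noise
(default SD 0.05 SUV). A liver blob (8 mm radius at this scaled-down
geometry; the reference ROI used on it is 10 mm rather than the clinical
30 mm) sits away from the spine near the D12 level.

Default geometry: 60 slices of 3×1×1 mm voxels, planes at occiput 6, C7
26, D12 54; canal a = 0.35, b = 0.15 (radius ≈ 12–16 mm); cord semi-axes
0.15 × 0.13 working units (6.0 × 5.2 mm, i.e. 12 × 10.4 mm diameters) with
center offset (0.01, −0.01). Two considerations fixed the cord size.
First, all default curve parameters sit on accumulator cell centers, the
condition under which exact-cell recovery is well defined. Second, the
boundary-layer estimate of partial-volume loss — mean recovery of a convex
region ≈ 1 − 0.4·σ·P/A with σ = FWHM/2.355 — shows that at 4 mm FWHM a
cord must be at least two FWHM across for a mask-mean SUV to land within
10 % of truth; the default cord meets that bound with margin (predicted
whole-cord NSUV error ≈ 5 %, observed 5.0 %). A substantially thinner cord
(e.g. 8 × 5.6 mm) would have recovery ≈ 0.6 and NSUV errors of ~12–20 %;
that is physics, not an algorithmic defect, and it is the same
partial-volume limitation a real dorsal cord presents at clinical PET
resolution.

What passing the phantom suite does **not** show about real data: the
phantom has piecewise-constant tissues, perfect coregistration, a straight
spine with a constant cross-section, an always-closed vertebral ring, a
fixed cord–CSF CT contrast (configurable down to 0), Gaussian rather than
Poisson-reconstruction noise, and no respiratory or patient motion. Curved
spines, open posterior arches, low cord contrast on low-dose CT, and
registration error will all degrade real-world performance relative to the
reported recovery rates.

## Cohort simulator and desk-scale statistics

The cohort generator draws each subject's whole-cord NSUV from
Normal(0.82, 0.28) for cases and Normal(0.70, 0.14) for controls
(truncated at 0.05, redrawing), the published group-level distributions.
Cervical/dorsal segment NSUVs echo the published segment means (0.99/0.72
cases, 0.85/0.62 controls), rescaled per subject so their volume-weighted
mean reproduces the drawn whole-cord value exactly; each member carries a
full phantom truth record realizing those NSUVs through the cord uptake.
At this effect size (Cohen's d ≈ 0.54) a two-sample t test at n = 30/30
has power ≈ 0.55, so group separation is expected in a majority — not all
— of simulated cohorts, and the suite asserts exactly that over 400 seeds.

Dichotomization at the fifth decile uses the lower-interpolation median so
the threshold is an observed value (with n = 30 the printed 0.67 cannot
disambiguate the interpolation rule; the convention is documented rather
than inferred). Mortality percentages round half-up. Kaplan-Meier,
log-rank and Cox fits are thin wrappers over standard survival routines,
included as report hooks only — they are validation statistics around the
imaging method, not part of it. Reproducing published hazard ratios would
require the original individual survival times, which are not public.

## Numerical choices and degenerate inputs

* Accumulator counts are int64; determinism relies only on argmax over
  integers and the two-stage tie-break above.
* Grids store bounds plus cell side; cell count per dimension is
  ceil((upper−lower)/side) with a 1e−12 guard against float spill.
* An all-uniform slice yields an empty edge set → an all-zero accumulator
  → a no-curve-found error, which the volume driver converts to an empty
  slice record.
* A circular canal (b = 0) falls between cells of the default b-grid
  (centers at ±0.01); recovery within one cell is the guaranteed outcome.
* The polar-residual identity is validated to 1e−8·a⁶ over |b| ≤ 0.9; as
  |b| → 1 the lobe radius diverges and the a⁶ scaling is no longer the
  right yardstick.
* Problem sizes in the tests and the reproduction script (a 64×64×60
  phantom, 49 analyzed slices, cohorts of 30 + 30, 400-seed power scans)
  were chosen as the smallest scales at which every property is
  informative.

## Known limitations

Axial-slice detection only (no sagittal reformatting); no automatic
vertebra labeling — the three planes are user input; no lumbar cord (CT
resolution does not support it, and the D12 plane is the caudal limit by
construction); no partial-volume correction — NSUVs of structures thinner
than ~2 FWHM are biased low; FDG only; anisotropic in-plane voxels are not
supported by the slice chain.
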