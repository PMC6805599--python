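# Methods

`hemivol` implements half-body MRI volumetry of abdominal adipose tissue: it
measures abdominal subcutaneous (ASAT) and visceral (VAT) fat volumes from
fat-selective transverse MR image stacks, splits them into left and right
body halves at a median line, and calibrates/applies a linear conversion that
predicts the whole-body volume from a single half. Because no patient data
are distributed, the package ships a synthetic phantom generator with exactly
known ground truth; every pipeline stage is validated against it.

## The half-to-full conversion model

For each compartment (ASAT, VAT) and side (L, R), the half-body volume is
regressed on the whole-body reference volume by ordinary least squares,

    side = f · REF + b,

and the conversion parameters (slope *f*, dimensionless; intercept *b*, cm³)
are inverted to estimate the whole from a measured half:

    EST = (side − b) / f.

Two identities follow whenever left + right = reference holds exactly in the
calibration cohort, and are enforced as tests: *f*_L + *f*_R = 1 and
*b*_L + *b*_R = 0 (the published parameter sets, e.g. {0.5253, −211.1 cm³}
and {0.4747, +211.1 cm³} for ASAT, obey both), and in-sample estimation
preserves the cohort mean, mean(EST) = mean(REF).

The published equation for the estimate is written as
`EST = side · 1/f + b`. Evaluated literally with the published parameters and
cohort-mean side volume it gives ≈ 12,363 cm³, while the published mean
estimate is 12,976.4 cm³; the inverse-prediction form above reproduces that
value (12,975.6 from the rounded inputs). We therefore treat *f* and *b*
strictly as the OLS slope and intercept of side-vs-reference (as the fitting
procedure defines them) and invert accordingly. The literal form remains
available via `estimate_full(..., as_printed=True)` for comparison only.

Agreement between measured and estimated totals is summarised Bland–Altman
style: mean difference, SD of differences (n−1 denominator), limits of
agreement at mean ± 1.96 SD, plus a Shapiro–Wilk normality check of the
differences (scipy's implementation of the standard algorithm; the n = 3
closed form, W = 1 for an equispaced sample, is asserted in tests). Group
contrasts (e.g. female vs male reference volumes) use a two-sided two-sample
t-test, pooled-variance by default with Welch available by option. Fits are
pooled across groups by default, matching a single parameter set for the
whole cohort; per-group tables can be fitted by filtering the cohort table.

## Image-analysis operators

The original measurements were made with an interactive contouring tool,
whose reader decisions cannot be reconstructed. The package defines
deterministic automatic counterparts (and accepts imported masks, flagged by
provenance):

* **Fat segmentation** — global threshold on the stack, `intensity ≥ thr`.
  Default is Otsu's criterion on a 256-bin histogram over the observed range.
  The search is implemented directly rather than through scikit-image for one
  numerical reason: on noiseless multi-level images the between-class
  variance is constant across the empty histogram gap between tissue levels,
  and scikit-image returns the first tied bin — a threshold touching the lean
  peak. We return the upper edge of the *middle* tied split, i.e. a mid-gap
  threshold, which keeps noiseless segmentation exact. Equivalence with an
  exhaustive intra-class-variance search is property-tested.
* **Body mask** — per slice, the largest 4-connected component of
  above-background voxels, holes filled. The background threshold defaults to
  the lower threshold of a three-class Otsu split (background / lean / fat).
* **SAT/VAT separation** — per slice: fat components (4-connected) touching
  the body boundary are subcutaneous candidates; the abdominal cavity is the
  body region remaining after their removal, morphologically closed (disk,
  default radius 3 voxels — bridges thin muscle-wall gaps in noisy images;
  exposed as a parameter) and hole-filled. VAT = fat inside the cavity,
  SAT = all other fat. The labels are disjoint and exhaust the fat mask by
  construction. All processing is slice-wise 2-D with 4-connectivity — one
  stated convention throughout.
* **Median line** — a straight sagittal plane per slice. Its base position is
  the lateral midpoint between the dorsal tip of the spinous process and the
  center of the corresponding vertebral body (L4/L5 level); per-slice lateral
  offsets correct for scoliotic deviation. Anchors further than 5 mm apart
  laterally trigger a warning. A voxel whose center lies exactly on the line
  is assigned to the *left* half — an arbitrary but fixed tie-break that
  keeps left + right = total exact. No vertebra detection is attempted;
  landmarks are metadata.
* **Volumetry** — volume = Σ slice area × axial step over an inclusive
  landmark-bounded slice range (upper T9-analog to lower pelvic-floor
  analog). The default axial step is the center-to-center slice spacing
  (thickness 10 mm + gap 0.5 mm = 10.5 mm), attributing the unimaged gap to
  the adjacent slice; a thickness-only 10.0 mm mode is provided because the
  original report does not state which convention its volumes used.
  Per-slice left/right area profiles are indexed relative to the umbilicus
  slice.
* **FOV completeness** — a body side is flagged incomplete if any SAT voxel
  touches that side's lateral grid border, mirroring the exclusion rule for
  subjects whose subcutaneous fat exceeded the field of view. `crop_fov`
  emulates the lateral-offset acquisition workaround that motivates the
  half-body method.

Coordinates are patient-based LPS; array axis 0 is lateral with increasing
index toward the patient's left, and all masks carry the orientation flag.

## The synthetic phantom

Each transverse slice is two nested ellipses: outer = skin, inner = abdominal
muscle wall. SAT is the ring between them; VAT is a union of random
ellipsoidal blobs inside the cavity, kept a lean margin (default 10 mm) away
from the wall so the compartments remain separable. Both ellipses taper
axially as 1 − 0.10·u², peaking at the umbilicus slice. Defaults emulate the
study acquisition and population: 50 slices of 10 mm with 0.5 mm gaps
(52.5 cm coverage), 128×128 matrix at 3.5 mm in-plane, fat/lean intensity
1000/100 with additive Gaussian noise of SD 30 (3% of the fat–lean gap; a
plain-noise stand-in — no Rician magnitude statistics, bias fields or coil
profiles), arms excluded, landmarks stored as slice indices.

Volume targets are met by construction rather than approximation:

* **ASAT** — the outer ellipse is scaled by the smallest factor at which the
  voxelised ring reaches the target volume. The voxel count is a
  non-decreasing step function of the scale, so the realised volume is
  monotone in the target and overshoots it by at most ~1%.
* **VAT** — each body side receives a voxel budget k = round(fraction ×
  target / voxel volume); blobs are added until the budget is met and the
  last blob is trimmed from its rim inward. Ground-truth side volumes
  therefore hit their budgets exactly, and a 0.5 left fraction yields
  *identical* left and right VAT.
* **ASAT asymmetry** — a lateral offset of the inner ellipse, solved in
  closed form (ellipse segment areas + Brent root-finding) from the requested
  left fraction; the voxelised fraction matches to a few tenths of a percent.

Ground truth is exact voxel counting × voxel volume (in-plane spacing ×
center-to-center step), with totals stored as left + right so conservation
holds with zero tolerance. The true median line follows the per-slice body
center (the scoliosis offsets), and the stored anchor points let the
median-line operator reproduce it exactly.

Cohorts draw per-subject totals uniformly from the published ranges
(ASAT 7,812–24,161 cm³, VAT 1,137–7,518 cm³ — or the per-gender Table-1
ranges when groups are configured) and side fractions from truncated normals
whose means and truncation bounds are the published cohort mean and min–max
(left ASAT 0.508 on [0.482, 0.537], left VAT 0.564 on [0.514, 0.659]); the
SDs (0.012 and 0.025) are chosen so roughly the full truncation interval is
exercised (±2σ ≈ the published spread). Per-subject seeds are spawned from
the master seed, so cohorts are bit-reproducible. Subjects receive a small
sinusoidal scoliosis (amplitude uniform on 0–4 mm).

The axial ASAT profile of real subjects peaks near the umbilicus; the
phantom's quadratic taper reproduces that qualitatively but is not claimed to
match any reported per-slice distribution quantitatively.

## What passing tests do and do not show

Noiseless phantoms at 2 mm resolution are recovered exactly (Dice = 1,
volumes within 2% of the closed-form ellipse geometry), and at a noise SD of
10% of the fat–lean gap compartment volumes stay within 5% of truth. On
cohorts drawn from the published population ranges, the half-vs-whole
correlations reach the published bounds (ASAT R² ≥ 0.99, VAT R² ≥ 0.97), both
on the volumes-only route (n = 200) and through the full imaging pipeline
(26 subjects at full resolution, ~10 s on one CPU). These results validate
the pipeline's correctness and the population-level geometry of the
half-body argument — not reader variability, intensity inhomogeneity,
arm/organ exclusion or any other property of clinical images the phantom
does not model. The cohort-specific published values (the exact four-decimal
parameter sets, Bland–Altman SDs of 361/267 cm³) depend on the original
patients and are not reproducible without them.

## Numerical choices and degenerate inputs

* Otsu on a constant image raises (degenerate histogram); ties resolved
  mid-plateau as described.
* Compartment fractions are NaN and flagged undefined when a compartment
  total is zero; empty slices yield empty masks; an empty label map is
  vacuously FOV-complete on both sides.
* Conversion fitting requires n ≥ 3 and a non-constant reference; estimation
  requires f ≠ 0; Shapiro–Wilk fields are withheld for n < 3 or constant
  differences.
* Geometry validation is explicit: the offset inner ellipse must fit strictly
  inside the outer one on every slice (violations name the slice), the body
  must fit inside the grid, and VAT budgets beyond the margin-eroded cavity
  capacity fail with the capacity stated.
* Limits-of-agreement factor is fixed at 1.96; SDs use n − 1 throughout.

## Problem sizes used by the shipped checks

The bundled demo cohort is 6 subjects at 64×64×10 (scaled-down volume
targets) so the command-line smoke runs complete in seconds. The end-to-end
validation cohort is the full 26 subjects at 128×128×50 with the published
population ranges. Simulation-level correlation checks use n = 200
volumes-only cohorts.
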