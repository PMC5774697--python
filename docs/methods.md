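# Methods

## Model

A kidney coronal section is modelled as an ellipse whose major axis `a`
is the pole-to-pole distance and whose full width is the minor axis.
The renal pelvis cuts a concave notch into the medial side, so the
width that can actually be measured on parenchyma, `b`, falls short of
the ellipse width by the notch depth. Three areas are defined:

- `A = π·a·b/4` — standard elliptical area, using the reachable minor
  axis; it underestimates the parenchymal area whenever a notch exists.
- `A_e = π·a·b_e/4` — modified elliptical area, using the minor axis
  extended across the pelvic cavity to the line that closes the notch.
- `A_m` — the measured (true) parenchymal area of the mask.

Total kidney collagen is modelled as linear in `A_e`:
`collagen = slope·A_e + intercept`, with defaults `slope = 7.7 μg/mm²`
and `intercept = −188.5 μg` (murine CKD calibration; the slope's units
follow from dimensional balance of the line). The model is a value
object, so other species or disease models can be recalibrated with
`fit_collagen_line` without code changes. Estimates below the
calibration root (≈24.48 mm²) are negative; they are returned unclamped
but tagged with a warning, because silently clamping would hide
calibration misuse. All lengths are mm and areas mm² internally; unit
conversion happens only at I/O boundaries.

## Measurement procedure

Given a binary mask with isotropic calibration (mm/pixel):

1. **Preprocessing** (for raw photographs): threshold at half the value
   range, keep the largest 8-connected component, fill interior holes
   smaller than 1% of the foreground. A human observer implicitly does
   all three.
2. **Major axis** — the longest chord of the foreground, computed over
   convex-hull vertices (the longest chord of a region equals that of
   its hull). Ties are broken by the lexicographically smallest
   (row, col) endpoint pair, so symmetric shapes measure
   deterministically.
3. **Minor axes** — the mask is resampled (nearest-neighbour) into a
   frame where the major axis is horizontal; scan lines are then image
   columns. On each line, `b` is the longest *contiguous* foreground
   run (a pelvis splitting the line into two runs is never summed) and
   `b_e` is the chord of the line through the convex hull of the
   foreground: the hull edge spanning the concavity is the computable
   analogue of the bar an observer draws to close the notch. The
   reported line is the one maximizing `b_e`; on a raster, all lines
   whose hull chord is within 2 px of the maximum are indistinguishable
   maximizers, and among those the line with the deepest pelvic
   extension (smallest `b`) is chosen — without this band, ~1 px of
   boundary noise can push the notch-bearing line just below the argmax
   and the measurement would silently miss the pelvis. A midpoint rule
   (scan line through the major-axis midpoint) is available as an
   option.
4. **True area** — foreground pixel count × pixel_size².

Numerical conventions: pixel centers sit at integer coordinates; the
major axis is a center-to-center distance while scan-line runs are
pixel-extent counts (`n·pixel_size`), and scan-line endpoints are
extended half a pixel beyond the extreme centers so the segment length
equals the reported `b_e`. Each convention differs from the continuous
geometry by at most one pixel; every length tolerance in the tests is
2·pixel_size. The convex hull uses pixel-center coordinates, under
which the hull of a digitally convex raster equals the raster — convex
masks therefore measure `b = b_e` exactly. On near-circular sections
discretization can make the widest run exceed the hull-vertex chord by
a pixel; `b` is clamped to `a` in that case.

## Synthetic silhouettes

`make_kidney_mask` rasterizes an analytic implicit shape at pixel
centers (rotation is applied to the sampling coordinates, so it costs
no resampling error): an ellipse with axes `a × b`, minus a pelvic
cavity at the midpoint of one long side. The cavity is a half-ellipse
of mouth width `w` along the boundary and depth `d` inward. A slender
cavity was chosen deliberately over a circular-disc bite: at realistic
notch depths (1–3 mm) a disc of matching mouth width bulges far into
the silhouette and removes ~7–10% of the area, which would make `A_e`
overshoot `A_m` well beyond what real sections show; the half-ellipse
keeps the cavity pelvis-like (removed area ≈ π·w·d/4, a few percent)
while preserving the analytically known relation `b_e − b = d` that the
oracle tests rely on. Boundary noise, when requested, is a smooth
low-frequency radial perturbation (8 Fourier harmonics, scaled to a
given sd in mm). One caveat: the convex hull closes the notch with a
chord slightly below the un-notched ellipse top (≈0.03 mm of sag at the
default `w = 1.5` mm), which is far inside the measurement tolerance
but grows quadratically with `w` — wide-mouthed notches measure
`b_e < b_generating` by construction, not by error.

## Cohort simulation

`simulate_cohort` draws per-kidney shapes from healthy and diseased
group distributions and sets
`collagen = slope·A_e + intercept + N(0, σ)`. Defaults emulate a murine
CKD study structure: 10 healthy kidneys near 12 × 6 mm (`A_e` ≈ 56.5
mm², collagen ≈ 247 μg) and 18 diseased kidneys near 13.5 × 6.75 mm
(`A_e` ≈ 71.6 mm², ≈ 363 μg — about 46% more), with σ = 58 μg chosen
analytically so the pooled collagen~`A_e` Pearson r sits near 0.8
(between-plus-within-group `A_e` sd ≈ 10 mm² maps to a 77.5 μg signal
sd; r² = signal²/(signal²+σ²)). Record areas use the exact analytic
notched-ellipse geometry (shapely polygon difference); rasterized masks
are optional. Each kidney consumes an independent random substream
keyed by `(seed, kidney index)`, so enlarging a group leaves earlier
kidneys unchanged. The generator emulates silhouette geometry and the
linear collagen–area law only; it does not model staining patterns,
irregular pelvic branching, sectioning artifacts, or non-elliptical
cortical bulges, so passing tests demonstrate correctness of the
measurement and statistics, not biological realism of any particular
kidney.

## Validation statistics

Pearson r is the product-moment coefficient; Spearman rho is Pearson on
mid-ranks (ties averaged). Both take two-sided p-values from
`t = r·√(n−2)/√(1−r²)` with n−2 degrees of freedom — exact under
bivariate normality for Pearson, and a standard approximation for
Spearman that is adequate at n ≈ 30. At very small n the t-based
p-value drifts from the exact permutation law, whose two-sided
granularity is 2/n! (e.g. no p below 0.083 exists at n = 4); the test
suite characterizes this drift against an exhaustive-permutation oracle
(within 0.02 for clearly associated vectors at n ≥ 6, looser bounds
below). Percent agreement is the mean ± SEM (sd with n−1 denominator
over √n) of per-kidney `100·calculated/measured`, tested two-sided
against 100% via a one-sample t-test on the ratios (a paired t-test on
the raw areas is selectable); with zero ratio variance the p-value is
reported as 1 on target and 0 off target. The calibration fit is plain
OLS with coefficient standard errors and R². α = 0.05 is used for
wording in reports and never gates computation; n is always taken from
the data.

## Problem sizes and defaults

Rendered-mask tests use 0.05 mm/px (a 12 mm kidney spans ~280 px), fine
enough that all length tolerances (2 px = 0.1 mm) and area tolerances
(1–2%) hold with margin; the pixel-counting oracle runs at 0.01–0.03
mm/px where pixel area converges to the closed form within 1%. The
agreement study uses 100 rendered kidneys with notch depths 1–3 mm;
calibration recovery uses 200 simulated cohorts of 28 kidneys. These
sizes make every statistic stable to well within its asserted tolerance
while keeping a full run in the tens of seconds.

## Known limitations

- The notch model is a single smooth medial cavity; real pelvises
  branch and may open asymmetrically, and severely deformed kidneys
  violate the elliptical premise altogether.
- The default collagen line is a single-timepoint murine calibration;
  applying it to other ages, models or species requires refitting.
- Spearman significance via the t-transform, and all small-n p-values,
  are approximations (see above).
- Masks are assumed given: the package measures silhouettes, it does
  not segment kidneys out of full histology photographs, and findings
  from stained sections may not transfer unchanged to noninvasive
  imaging geometries.
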