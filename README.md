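# renalmorph

Morphometry of kidney coronal sections with a modified elliptical
formula, and estimation of total kidney collagen — a surrogate for renal
fibrosis — from just two axial measurements.

## The problem

In chronic kidney disease (CKD), scarring means accumulation of
fibrillar collagen in the renal interstitium. The only direct way to
measure it is invasive (biopsy, or biochemical assay of excised tissue),
yet kidney *size* abnormalities are easy to see noninvasively. The
standard practice of treating the kidney as an ellipse,

```
A = π·a·b / 4
```

with `a` the major (polar) axis and `b` the minor axis (renal width),
systematically underestimates the true parenchymal area `A_m`, because
the concave renal pelvis shortens the measurable width. Extending the
minor axis across the pelvic notch to the line that closes it — the
extended minor axis `b_e` — gives a modified elliptical area,

```
A_e = π·a·b_e / 4
```

which tracks the measured parenchymal area closely. Since total kidney
collagen is linearly related to parenchymal area, collagen content can
be estimated from the two axial measurements alone:

```
collagen (μg/kidney) = 7.7 · (π·a·b_e/4) − 188.5
```

(default murine CKD calibration; both coefficients are configurable).

`renalmorph` is for researchers quantifying renal fibrosis in rodent CKD
models from section photographs or segmentation masks, and for anyone
developing imaging surrogates of tissue collagen. It provides:

- **geometry** — the elliptical area formulas and the collagen
  calibration line as typed value objects;
- **morphometry** — automatic measurement of `a`, `b`, `b_e` and `A_m`
  from a binary section mask (longest chord, perpendicular scan lines,
  convex-hull closure of the pelvic notch, calibrated pixel counting);
- **shape_synthesis** — a generator of notched-ellipse silhouettes and
  simulated healthy/diseased cohorts with known ground truth, so the
  entire pipeline is testable without animal data;
- **stats_validation** — Pearson/Spearman correlations with t-transform
  significance, percent-agreement summaries (mean ± SEM), and OLS
  calibration fitting;
- a thin **CLI** (`renalmorph measure|simulate|estimate|validate`) plus
  narrative scripts in `examples/`.

## Worked example

Measuring a synthetic section with a known 2 mm pelvic notch
(`python examples/measure_section.py`):

```
measured axes:  a = 12.00 mm, b = 4.95 mm, b_e = 7.00 mm
standard area   A   = pi*a*b/4   = 46.6 mm^2
modified area   A_e = pi*a*b_e/4 = 65.9 mm^2
measured area   A_m (pixel count) = 63.6 mm^2

The pelvic notch shortens the reachable minor axis b, so A reads
73% of the true area; extending the minor axis across the
pelvis (b_e) restores it: A_e is 104% of A_m.
```

The generating silhouette had `a = 12`, `b_e = 7` and a 2 mm-deep notch:
the measured axes recover all three within two pixels (0.1 mm), the
standard formula underestimates the true area badly, and the modified
formula agrees with it to a few percent.

Estimating collagen from two axial measurements
(`python examples/estimate_collagen.py`):

```
axes: a = 13.0 mm, b_e = 6.9 mm
modified elliptical area A_e = pi*a*b_e/4 = 70.5 mm^2
collagen = 7.7 * A_e + (-188.5) = 354.0 ug/kidney
```

`examples/simulate_and_validate.py` runs the full validation battery on
a simulated 10-healthy + 18-diseased cohort and refits the calibration
line from the noisy data.

The same operations are available from the shell:

```bash
renalmorph simulate --seed 7 --out-dir cohort/ --write-masks
renalmorph measure cohort/*.png --mm-per-pixel 0.05 --out measured.csv
renalmorph estimate measured.csv --out estimated.csv
renalmorph validate cohort/cohort.csv
```

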