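# Methods

This note documents the models, conventions and numerical choices behind
`pomograde`, and what the synthetic test bed does and does not establish.

## Colorimetric chain

The pipeline expresses every frame in the planes each decision needs:
HSV saturation for figure/ground, tristimulus Y for brightness, CIELAB a\*
for redness — all under the rig's actual illuminant.

**Transfer function.** `ColorImage` carries a `transfer` tag. CMOS sensors
respond linearly to radiance, so frames straight from the camera are
tagged `linear` and go to XYZ directly; files that passed through an sRGB
pipeline are tagged `srgb` and first linearized with the IEC 61966-2-1
piecewise rule. This matters: the class color statistics the thresholds
were calibrated on (Table below) are only reproduced when the camera RGB
is treated as linear. Running gamma-encoded images through the default
`linear` route shifts a\* of dark saturated reds from ~29 down to ~8 and
would put the red threshold on the wrong side of the class; conversely the
grading thresholds (a\* > 15, Y > 0.5) presume the linear route.
`GradingConfig.input_transfer` exposes the choice.

**RGB → XYZ (D65).** The standard sRGB matrix; its column sums define the
working D65 white (0.95047, 1, 1.08883). Unit RGB maps to Y = 1 within
1e-5.

**Chromatic adaptation.** The lamps are ≈5300 K (≈ D55), the matrix is a
D65 matrix, so XYZ is adapted D65 → D55 with the von Kries transform
M = M_A⁻¹·diag(ρ_D/ρ_S, γ_D/γ_S, β_D/β_S)·M_A. The default cone matrix
M_A is the classic von Kries (Hunt–Pointer–Estévez) matrix — chosen
because it reproduces the adaptation matrix this system was built with to
4×10⁻⁵ per element — with Bradford as a selectable alternative. Every
constructed `AdaptationMatrix` is checked to carry the source white to the
destination white within 5×10⁻⁴ componentwise.

**CIELAB.** Standard CIELAB under the D55 white (0.95682, 1, 0.92149),
with the classical constants (branch point 0.008856, linear slope 7.787,
offset 16/116); the two branches of f agree at the branch point to ~1e-3,
which is the usual discontinuity of the classical constants and irrelevant
at the thresholds used here.

**HSV.** Hue is a fraction of a turn in [0, 1), red at 0. Two saturation
conventions are exposed: the hexcone S = (max−min)/max (what `rgb2hsv`
routines compute; the default of `rgb_to_hsv`) and the intensity-normalized
HSI form S = 1 − 3·min/(R+G+B). Segmentation defaults to the HSI form
(`saturation_mode="hsi"`): on the dark bluish background (mean RGB ≈
(0.013, 0.011, 0.023)) the hexcone form is ≈0.52 — dark near-neutral
pixels have ill-conditioned max−min ratios — and a 0.5 threshold would
flood the background, while the HSI form sits near 0.30 and separates
cleanly. The measured background S statistic (0.307) matches the HSI
form, so that is also what the 0.5 threshold was calibrated on.

## Segmentation

Three strict (`>`) rules, OR-combined: S > 0.5, Y > 0.5, a\* > 15. Red
surface fires the a\* rule, bright surface the Y rule, and any vivid pixel
the S rule; union rather than intersection because no single rule covers
both color classes. Cleanup applies, in order: a 3×3 binary opening
(removes isolated pixels and 1-px chains of background speckle — without
it, speckle chains attached to the fruit outline occasionally stretched
the bounding box by up to ~5 mm, enough to flip a size class; with it the
measured inflation is below 1 mm), removal of 8-connected components under
`min_area_px` (default 64), and hole filling. The composite is idempotent.
The largest 8-connected component is the fruit; area ties resolve to the
earliest component in row-major scan order. Bounding boxes are 0-based,
half-open.

## Grading

* **Red fraction**: pixels with a\* > 15 inside the fruit, over fruit area.
* **Yellow fraction**: pixels with Y > 0.5 inside the fruit, after
  dividing the Y plane by its maximum within the fruit
  (`y_norm="apple_max"`). The absolute Y of the yellow class is ≈0.27 —
  below any fixed 0.5 cut — so the 0.5 threshold is meaningful only on a
  brightness-normalized plane ("normalized values"); normalizing within
  the fruit keeps it per-frame robust. `y_norm="none"` gives the raw
  unit-scale behaviour for experimentation.
* **Color group**: red iff red_fraction ≥ yellow_fraction (tie → red,
  documented and deterministic).
* **Variety**: red_fraction < `red_presence_min` (0.01) → Golden;
  red_fraction ≥ `starking_red_min` (0.50) with yellow_fraction <
  `red_presence_min` → Starking; otherwise Jonagold. The two constants
  are not published values; they are exposed in config. Note that under
  `apple_max` normalization a fully red fruit's own brightest pixels pass
  the yellow rule, so Starking tends to be reported as Jonagold; the
  commercial (color, size) group — the quantity the system is scored
  on — is unaffected.
* **Size**: bounding-box extents × `pixel_length_mm` (0.312). The
  measured-size reading of "pixel number in x- and y-axes × pixel length"
  is per-axis extent, not area — a size class needs a length. "Large" at
  max(width, height) ≥ 75 mm (inclusive); the cutoff is a realistic
  commercial default, exposed in config.

## Synthetic scenes

The generator renders an elliptical fruit on background noise; the surface
is partitioned into ~12 nearest-seed (Voronoi) cells of random interior
points, and cells are greedily painted red until the requested red area
fraction is covered (granularity ≈ one cell). Per-pixel RGB is Gaussian
per class at the measured class means and standard deviations (unit-scale
linear RGB), clipped to [0, 1], quantized to 8 bits:

| class      | R             | G             | B             |
|------------|---------------|---------------|---------------|
| red        | 0.099 ± 0.040 | 0.009 ± 0.004 | 0.010 ± 0.004 |
| yellow     | 0.347 ± 0.128 | 0.288 ± 0.108 | 0.010 ± 0.004 |
| background | 0.013 ± 0.004 | 0.011 ± 0.003 | 0.023 ± 0.006 |

Channels within a pixel share a common shading factor (correlation 0.99).
This is not optional realism: with independent channels the yellow class's
a\* would scatter with σ ≈ 19, while the measured per-class Lab scatter is
σ(a\*) ≈ 2.8 — per-pixel variation on a curved fruit is dominated by
shading, which moves all channels together. With ρ = 0.99 the generated
classes reproduce the measured Lab statistics (red a\* 29.7 ± 5.3 vs
29.1 ± 5.8; yellow a\* −4.2 ± 2.4 vs −4.8 ± 2.8; yellow L 58 ± 11 vs
58 ± 10).

Batches draw per-group fruit diameters uniformly from
regular (60, 70) mm and large (80, 90) mm — each 5 mm clear of the 75 mm
cutoff, so size labels are unambiguous — with ±4 % eccentricity; group
counts follow the requested mix by largest-remainder rounding. Yellow
fruit are Golden; red fruit alternate Starking (fully red) and Jonagold
(65–85 % red). Frames are sized to the fruit plus a 12 px margin, and all
randomness derives from one seed (per-scene child seeds below 2³¹).

What the generator does **not** emulate: specular highlights, shading
gradients across the fruit, stem/calyx regions, soft (antialiased) fruit
boundaries, motion blur, multiple fruit per frame. Passing the synthetic
end-to-end tests therefore shows the pipeline's logic and calibration are
correct under the measured class statistics; it does not certify
performance on real frames, where the published red/yellow pixel
identification rates (97 % / 94 %) came from the authors' own camera
images and cannot be recomputed here.

## Problem sizes and determinism

The end-to-end recovery test and the acceptance script grade 595 scenes
(the size of the original survey), about 200–300 px across at the 0.312
mm/px calibration — roughly 25 s of compute. Segmentation quality is
scored as intersection-over-union against the generator's true ellipse
mask (≥ 0.95 required; measured ≈ 0.99). All stochastic tests are seeded;
CLI runs with the same seed and configuration produce byte-identical
reports.

## Known limitations

* Single fruit per frame by design; two touching fruit would be merged.
* The variety rule constants are heuristics; only the (color, size) group
  is validated quantitatively.
* Fixed thresholds presume the rig's illumination; no illumination
  correction or auto-calibration is provided.
* Lab uses the classical CIELAB constants (0.008856 / 7.787), not the
  exact rational ones; differences are ~1e-3 in f, far below the decision
  thresholds.
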