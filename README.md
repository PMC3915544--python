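# pomograde

Machine-vision grading of apples by surface color and size, as done on a
single-lane conveyor rig: one CMOS camera frame per fruit, diffuse
fluorescent illumination close to CIE D55, and a fixed pixel calibration of
0.312 mm. The package classifies each fruit into one of four commercial
groups — red/regular, red/large, yellow/regular, yellow/large — and infers
the variety (Golden, Starking, Jonagold) from how much of the surface is
red versus yellow. It is aimed at produce-inspection engineers and at
anyone who needs a small, fully tested reference implementation of a
multicolor-space segmentation/grading pipeline, including a synthetic scene
generator so everything runs without a camera.

## The method

A frame is taken through several color spaces, each used for what it is
best at:

1. **Unit scaling / transfer handling.** 8-bit RGB is divided by 255.
   Raw camera frames are linear in radiance (`transfer="linear"`); images
   saved through an sRGB pipeline are first linearized with the
   IEC 61966-2-1 rule: c/12.92 for c ≤ 0.04045, else ((c+0.055)/1.055)^2.4.
2. **HSV.** Saturation separates the vivid fruit from the dark,
   desaturated conveyor background. Both the hexcone form
   S = (max−min)/max and the intensity-normalized form
   S = 1 − 3·min/(R+G+B) are available; segmentation defaults to the
   latter, which stays low on dark near-neutral pixels.
3. **CIE XYZ under D65.** Per pixel, [X Y Z]ᵀ = M·[R G B]ᵀ with the
   standard sRGB matrix (first row 0.4124564, 0.3575761, 0.1804375).
4. **Chromatic adaptation D65 → D55 (von Kries).** The lamps are ~5300 K,
   so colors are re-expressed under D55. With a cone matrix M_A (classic
   von Kries / Hunt–Pointer–Estévez by default, Bradford selectable) and
   cone responses (ρ, γ, β) = M_A·white,

       M = M_A⁻¹ · diag(ρ_D/ρ_S, γ_D/γ_S, β_D/β_S) · M_A,

   built from the D65 white (0.95047, 1, 1.08883) and the D55 white
   (0.95682, 1, 0.92149).
5. **CIELAB under D55.** L\* = 116·f(Y/Yn) − 16,
   a\* = 500·(f(X/Xn) − f(Y/Yn)), b\* = 200·(f(Y/Yn) − f(Z/Zn)),
   f(q) = q^(1/3) above 0.008856, else 7.787·q + 16/116.

Segmentation ORs three strict threshold rules — S > 0.5, Y > 0.5,
a\* > 15 — cleans the mask (3×3 opening, minimum component area, hole
filling) and keeps the largest 8-connected component. Inside the fruit,
**red** pixels are a\* > 15 and **yellow** pixels are Y > 0.5 after
normalizing Y by its maximum within the fruit. The color group is red when
the red area fraction is at least the yellow one; size in mm is the
bounding-box extent × 0.312 mm/px, "large" at ≥ 75 mm. Every threshold is
configurable (`pomograde show-config`).

## Worked example

Generate six labeled synthetic scenes, grade them, and score the result:

```sh
$ pomograde synth --n 6 --seed 42 --out-dir scenes
wrote 6 scene(s) to scenes (truth at scenes/truth.csv)

$ pomograde grade scenes --report report
INFO pomograde: thresholds: a*>15, Y>0.5 (norm=apple_max), S>0.5; cone model=von-kries
graded 6 image(s) (0 failed); report at report.csv

$ head -4 report.csv
file,variety,color_group,size_class,width_mm,height_mm,red_fraction,yellow_fraction
scene_0000.png,Jonagold,red,regular,67.704,67.392,0.981166,0.242152
scene_0001.png,Jonagold,red,regular,66.768,64.584,0.859358,0.030348
scene_0002.png,Jonagold,red,large,87.36,89.544,0.981216,0.129232

$ pomograde evaluate --pred report.csv --truth scenes/truth.csv --out confusion
         group  graded  incorrect  rate
   red/regular       2          0   1.0
     red/large       2          0   1.0
yellow/regular       1          0   1.0
  yellow/large       1          0   1.0
global correct classification rate: 1 (6/6)
```

Reading the report row for `scene_0000.png`: 98.1 % of the fruit surface
passed the red rule and 24.2 % the (normalized) yellow rule, so the color
group is red; the bounding box is 217 × 216 px, i.e. 67.7 × 67.4 mm, below
the 75 mm cutoff, so the size class is regular.

The same pipeline is available as a library:

```python
import pomograde as pg

scene = pg.generate_scene(pg.SceneSpec(
    image_size=(240, 240), apple_center=(120, 120), apple_axes=(100, 95),
    variety="Jonagold", red_patch_fraction=0.7, yellow_patch_fraction=0.3,
    seed=5))
record = pg.grade_image(scene.image)
print(record.group, round(record.width_mm, 1), "mm")   # red/regular 59.0 mm
```

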