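# speleoclean

Virtual cleaning and analysis of speleothem-encrusted skeletal remains from
clinical CT.

Skeletal finds in karst caves are often sealed inside thick calcite crusts
precipitated from drip water. Mechanical or chemical preparation risks
destroying the specimen; a clinical CT scan does not. The obstacle is that a
partially fossilised bone and its calcite concretion can have nearly the same
Hounsfield-unit (HU) density, so plain threshold or region-growing
segmentation fails. `speleoclean` implements, as a reusable and fully
scriptable pipeline, a combined manual/threshold protocol for this situation:

1. **Sparse contours** — a reader traces the bone boundary as closed
   free-form polygons on every k-th axial slice (clockwise, starting at
   twelve o'clock); contours are stored in a plain JSON format.
2. **Shape-based interpolation** — the missing slices are filled by blending
   signed Euclidean distance fields of the keyframe masks:
   `d = (1−t)·d_a + t·d_b`, inside = `d < 0`. Keyframes are reproduced
   bit-exactly.
3. **Virtual cleaning** — the masked specimen is erased from a copy of the
   scan (fill value below the HU range), producing a crust-only *template*
   series; subtracting the template from the untouched original leaves a
   series containing only the specimen at its native HU values.
4. **Surface model** — a marching-cubes isosurface at an HU threshold,
   reduced to its dominant connected component and exported as binary STL.
5. **Validation** — models built independently by several readers are
   compared by unsigned cloud-to-cloud nearest-neighbour distances on
   area-weighted point samples (mean/SD/max and the fraction of points
   within 1 mm, cyclically R1→R2, R2→R3, R3→R1).
6. **Osteometry** — the von den Driesch measures Bp (greatest breadth of
   the proximal end), DC (depth of the femoral head) and SD (smallest
   diameter of the diaphysis) are taken from the mesh with explicit
   geometric definitions (projected calipers, consensus sphere fit, planar
   cross-section calipers).

Because real encrusted-specimen scans are rarely public, the package ships a
first-class **phantom generator**: a synthetic femur (shaft + neck + head +
trochanter bump, all with closed-form measures) inside a calcite crust whose
HU distribution overlaps the bone's, at anisotropic voxel spacing with blur
and noise — plus simulated imperfect readers. Every stage is therefore
testable end to end with known ground truth.

A self-contained **radiocarbon calibration** module calibrates a
conventional age against an IntCal-format curve on a 1-year grid
(`posterior(t) ∝ exp(−(age−μ(t))²/2(σ²+σ_curve(t)²))`) and reports
highest-posterior-density ranges with their relative probabilities in
cal BC/AD.

## Worked example

A complete three-reader phantom run from the shell. `spec.json` describes a
small encrusted femur (40 mm shaft of 14 mm diameter, 16 mm head, 3 mm
crust, 0.5 × 0.5 × 0.8 mm voxels):

```json
{"shaft_radius": 7.0, "shaft_length": 40.0, "head_radius": 8.0,
 "neck_radius": 4.5, "neck_length": 6.0, "head_offset": 7.0,
 "trochanter_bump_radius": 6.0, "trochanter_offset": 10.0,
 "crust_thickness_mean": 3.0, "spacing": [0.5, 0.5, 0.8], "seed": 4}
```

Readers trace every 10th slice with 0.2 mm vertex jitter:

```sh
speleoclean phantom --spec spec.json --out ph --seed 7 --vertex-noise-sd 0.2
for R in R1 R2 R3; do
  speleoclean clean   --ct ph/series --contours ph/$R.contours.json --out cl_$R
  speleoclean surface --ct cl_$R/cleaned --out $R.stl
done
speleoclean measure --stl R1.stl --out report.json
speleoclean compare --stl R1.stl --stl R2.stl --stl R3.stl \
    --out compare.csv --n-points 20000 --seed 1
```

which prints:

```
Bp=30.5 mm DC=14.8 mm SD=14.4 mm
  pair     n  mean_mm    sd_mm   max_mm  fraction_within_1mm
R1->R2 20000 0.244512 0.123338 0.777552                  1.0
R2->R3 20000 0.242731 0.125283 0.784644                  1.0
R3->R1 20000 0.244776 0.127943 0.856123                  1.0
```

The analytic truth of this phantom (`ph/truth_measures.json`) is
Bp = 31 mm, DC = 16 mm, SD = 14 mm — all three measures are recovered
within two voxels (2·max spacing = 1.6 mm) despite the overlapping crust
and the simulated reader noise, and the three independent models agree to
a mean deviation of ≈ 0.24 mm with every sampled point within 1 mm of the
next reader's model.

Calibrating a radiocarbon age (any `.14c`-layout curve):

```sh
speleoclean calibrate --age-bp 4781 --sigma 35 --curve intcal13.14c
```

prints the 1σ and 2σ HPD ranges in cal BC with each range's share of the
confidence mass.

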