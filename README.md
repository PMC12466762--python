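# bovimetry

Non-contact cattle body measurement from a single aligned RGB-D side view.

Manual measurement of body traits (withers height, hip height, body length,
cannon circumference) is slow and stresses the animal. Given a pixel-aligned
color + depth pair of a standing animal in lateral view, the pixel
coordinates of six anatomical landmarks, and the camera parameters, this
package computes the four traits in centimeters, together with the
OKS-based evaluation metrics used to score keypoint detectors. It is aimed
at precision-livestock researchers who already have a landmark detector (or
manual annotations) and need the geometric back end plus a fully synthetic
test bench.

## Method

1. **Depth completion.** Consumer depth sensors leave holes (value 0).
   A missing pixel `D[i,j] = 0` is filled with the arithmetic mean of the
   valid depths on the 16 outer-ring pixels of the 5×5 window centered at
   `(i, j)` — the offsets with `max(|m|, |n|) = 2`. Passes use Jacobi
   semantics (each pass reads only the previous pass's values), repeated
   until convergence or `max_passes`.
2. **Back-projection.** A pixel `(u, v)` with depth `Z` maps to the camera
   frame through the inverse pinhole model
   `X = (u − cx)·Z/fx`, `Y = (v − cy)·Z/fy`, `Z = Z`
   with default intrinsics `fx, fy, cx, cy = 525, 525, 319.5, 239.5`,
   then to world coordinates via the rigid transform `p_w = R·p_c + T`.
3. **Pass-through filtering.** Scene points are kept when their camera-frame
   depth lies in the open interval `(z1, z2)` — default `(0.1 m, 5 m)` — to
   discard background returns.
4. **Ground plane.** The floor elevation `z0` is the median height of the
   lower half of the cloud points near the hooves (hoof positions are
   derived from the cannon landmarks when not given explicitly).
5. **Traits.** Withers and hip height are the world-Z differences between
   the landmark and `z0`; body length is the 3-D Euclidean distance
   `L = √((X₁−X₂)² + (Y₁−Y₂)² + (Z₁−Z₂)²)` between shoulder point and pin
   bone; cannon circumference is `π·d` with `d` the distance between the
   bilateral cannon points (circular cross-section assumption).
6. **Evaluation.** Keypoint predictions are scored with object keypoint
   similarity
   `OKS = Σᵢ exp(−dᵢ²/(2 s² σᵢ²)) δ(vᵢ>0) / Σᵢ δ(vᵢ>0)`,
   AP at a threshold T (fraction of instances with OKS > T), mAP over the
   0.50:0.05:0.95 grid, and precision/recall from keypoint-level TP/FP/FN.

A synthetic phantom — a quadruped assembled from analytic prisms over a
ground plane, ray-cast through the same pinhole model with exactly known
landmark coordinates and trait values, plus seeded depth dropout and noise —
makes every stage testable with no animal data. The package also ships
numpy forward passes of the three attention operators used to strengthen a
lightweight pose detector (SimAM, coordinate attention and their CASimAM
composition, multi-head self-attention, and the dual-branch
DRAMiTransformer block), with their insertion-point descriptors.

## Worked example

Render a noiseless phantom with known dimensions and measure it back:

```
$ bovimetry synth --out demo --animal-id cow0 --seed 5
wrote cow0 capture to demo
$ bovimetry measure --frames demo --out rep
report written to rep/report.csv
$ cat rep/report.csv
animal_id,withers_height_cm,hip_height_cm,body_length_cm,cannon_circumference_cm,withers_height_re_pct,hip_height_re_pct,body_length_re_pct,cannon_circumference_re_pct
cow0,130.01,133.99,160.00,22.00,0.01,0.01,0.00,0.03
```

The phantom was built with withers 130 cm, hip 134 cm, body length 160 cm
and a 7 cm cannon diameter (circumference π·7 ≈ 21.99 cm); the pipeline
recovers all four traits with relative errors of 0.00–0.03 % (the
`*_re_pct` columns compare against `demo/truth.csv`). With 10 % depth
dropout and 5 mm depth noise the mean absolute relative error stays below
1 % per trait after depth completion. `bovimetry eval --pred ... --gt ...`
scores predicted keypoints the same way a detector benchmark would:

```
{"AP@0.5": 1.0, "AP@[0.50:0.95]": 1.0, "precision": 1.0, "recall": 1.0, ...}
```

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults, the
phantom's construction and its limits, and the numerical choices.
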