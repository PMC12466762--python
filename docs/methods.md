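# Methods

## Problem setting and assumptions

The pipeline estimates four body traits of a standing bovine from one
pixel-aligned RGB-D capture taken side-on: withers height, hip height, body
length (point of shoulder to posterior pin bone) and cannon circumference.
It assumes (i) the color and depth images are already registered pixel to
pixel, (ii) the animal stands roughly parallel to the image plane on a level
floor, (iii) six lateral-view landmarks are supplied in pixel coordinates by
an external detector or manual annotation, and (iv) camera intrinsics are
known, with an optional rigid camera-to-world transform. Heights are
defined as coordinate differences along the world up axis (+Z), not
point-to-plane distances along an estimated normal; for the level-floor
setting the two coincide, and the coordinate-difference convention is what
the trait definitions state.

## Depth completion

A depth value of 0 marks a missing measurement. A hole at (i, j) is filled
with the arithmetic mean of the valid values on the 16 outer-ring pixels of
the 5×5 window centered there (Chebyshev distance exactly 2); the inner 3×3
neighbors do not contribute. Decisions the definition leaves open:

* **Pass semantics.** Within a pass all fills read the pre-pass map
  (Jacobi), so output is independent of pixel scan order. A single pass is
  the strict ring-mean operator; the default `max_passes = 5` repeats it so
  hole blobs wider than the ring (e.g. the gap between fore and hind limbs)
  fill from their boundary inward. Completion stops early when no pixel
  changes.
* **Borders.** Windows are clipped at the image edge; only in-image ring
  positions enter the mean.
* **Validity.** "Valid" means strictly positive; NaNs are coerced to 0 on
  ingest. Valid pixels are never modified, so the missing set never grows.

## Geometry

Back-projection follows the inverse pinhole model with the calibrated
intrinsics (defaults fx = fy = 525 px, cx = 319.5, cy = 239.5 on an 848×480
sensor). The pass-through filter keeps camera-frame points with Z in the
*open* interval (z1, z2), exactly as the set notation defines it; defaults
z1 = 0.1 m (sensor minimum), z2 = 5 m. Kept plus removed always partitions
the input.

**Ground plane.** The floor elevation z0 is estimated from "hoof-adjacent"
cloud points: all points within `radius` (default 0.15 m, 3-D Euclidean) of
any hoof hint are collected, the upper half by height is discarded to reject
points on the limbs, and z0 is the median of the remainder (at least
`min_support = 50` candidates required). When hints are not supplied they
are derived from the landmarks: the cannon-pair midpoint (or any visible
landmark as fallback) is dropped onto the nearby cloud by taking the 1st
percentile of heights within a horizontal `radius` as the hint height. The
median makes the estimate invariant to duplicated floor points and robust to
a minority of limb points in the neighborhood.

**Landmark depth lookup.** A landmark keeps its subpixel (u, v); rounding
happens only when indexing the depth map. The default lookup is the median
of the valid completed depths in the 5×5 window around the rounded pixel.
The median is essential for the thinnest trait: the cannon diameter is only
~7 cm, so at 848×480 a single-pixel lookup leaves the circumference error
dominated by per-pixel depth noise (a 5 mm depth sd alone contributes ~2–3 %
mean error), while the 25-sample median suppresses it by roughly the square
root of the window size and is exact on locally planar surfaces. A
single-pixel mode (`lookup="nearest"`) is available. Whenever the center
pixel itself is invalid the landmark is flagged `depth-interpolated`; a
fully invalid window yields a missing landmark, which drops only the traits
that use it (a missing trait is reported as absent, never 0).

## Trait computation

Withers/hip height: (landmark world-Z − z0) × 100, in cm; a non-positive
result raises an orientation error (the up-axis convention is
misconfigured). Body length: 3-D Euclidean distance × 100. Cannon
circumference: π × distance between the bilateral cannon points, treating
that distance as the diameter of a circular cross-section — no elliptical
correction. Relative errors are |pred − gt|/gt × 100, reported to two
decimals.

## OKS evaluation

OKS is the visibility-weighted mean of per-keypoint Gaussian similarities
exp(−dᵢ²/(2 s² σᵢ²)). The object scale follows the standard convention
s = √(bbox area) (`sqrt_area`); a `raw_area` mode (s = area) is provided for
literal reproduction of formulations that square the area itself, which is
dimensionally inconsistent and not the default. σᵢ defaults to 0.05 for all
six landmarks (no published per-landmark values exist for cattle) and is
configurable. AP at threshold T is the fraction of instances with OKS
strictly greater than T — the indicator form, not the COCO
precision-recall-curve integral — so AP is non-increasing in T by
construction; mAP averages over categories or the 0.50:0.05:0.95 grid.
Matching is greedy: predictions in descending instance confidence each take
the unmatched ground truth with the highest positive OKS. Keypoint-level
counting makes every visible ground-truth keypoint exactly one TP (matched,
per-keypoint term above the decision threshold) or one FN, so TP + FN equals
the ground-truth keypoint count; a matched-but-wrong keypoint is also an FP,
as are keypoints of unmatched predictions. 0/0 rates are defined as 0 and
flagged.

## Synthetic phantom

The phantom emulates the study capture: an 848×480 aligned RGB-D side view
from ~1.5 m with the default intrinsics. The body is a union of
axis-aligned prisms on the z = 0 floor — a front trunk prism topped exactly
at the withers height, a rear prism at the hip height, and four
square-section legs — ray-cast analytically, so depth is exact and the six
landmarks have closed-form world coordinates. Design choices:

* **Camera rig.** With a 525 px focal length on 480 rows, the vertical
  field of view at 1.5 m spans only ~1.37 m, so a level camera cannot see
  both a 1.5 m withers and the floor. The rig therefore sits at 1.58 m
  height, pitched 22° down: the bottom of the frame meets the floor at the
  flank line (floor visible all around the hooves, which the ground
  estimator requires) and the frame top at the flank is ~1.65 m, above the
  tallest trunk. The extrinsics returned with each render encode this rig,
  so the camera-to-world path is exercised non-trivially.
* **Landmarks on faces, not edges.** The prisms extend a small margin
  (2–3 cm trunk, 1.2 cm legs) beyond the marked extremes so every landmark
  lies strictly inside a flat camera-facing face; depth windows around a
  landmark then never straddle a silhouette, and trait ground truth equals
  the configured `PhantomSpec` dimensions exactly by construction. The bilateral cannon markers are
  separated by exactly the cannon diameter; the rendered leg is slightly
  wider, standing in for the soft tissue around the measured girth.
* **Degradation.** Gaussian depth noise is added to valid pixels, then a
  seeded uniform fraction of valid pixels is zeroed (dropout). An optional
  structured-hole mode zeroes the pixel block between the leg pairs for
  multi-pass completion tests. A 10 m sensor range truncates far floor
  returns, as real hardware does. Identical spec + seed reproduces the
  frame, keypoints and measurements bit for bit.
* **What it does not model.** No surface curvature, texture, fur, posture
  variation, occlusion by fences, or detector error: passing recovery tests
  shows the geometric chain is correct and noise-robust, not that a detector
  will find landmarks on real animals. Real-data errors are dominated by
  landmark localization, which the phantom deliberately excludes.

Sampled phantom geometries span withers heights 1.24–1.48 m, hip heights up
to 1.50 m, body lengths 1.39–1.78 m and cannon circumferences 18–24 cm —
the spread of manual measurements on medium-frame beef cattle. Recovery
tests and the acceptance script use 20 such geometries per condition;
noiseless runs recover all traits to within 0.05 % and runs with 10 %
dropout + 5 mm noise stay under 1 % mean absolute relative error per trait,
against acceptance bands of 1 % and 2 %.

## Attention operators

The three detector-enhancement blocks are provided as deterministic numpy
forward passes over B×C×H×W maps, with seeded weight initialization and a
parameter census for testing; they are operators, not a trainable network.
SimAM uses the standard closed-form energy (per-channel mean and variance,
regularizer λ = 1e−4, n = HW − 1) and holds zero parameters. Coordinate
attention pools along H and W separately, reduces channels (default
reduction 8), and gates the input per direction. CASimAM composes them in
that order. MHSA flattens the spatial grid and runs scaled dot-product
attention (default 64 channels / 4 heads, the P3-level width of a
nano-scale detector); its attention rows sum to 1. The DRAMiTransformer
block runs a spatial branch (shared query/key projection, hence symmetric
"reciprocal" attention) and a channel branch (channels as tokens) in
parallel, mixes them with a learned sigmoid gate, and closes with a
two-layer FFN; both the attention mix and the FFN carry residual
connections, and forcing the gate to 0 or 1 reduces the block to a single
branch plus FFN. Insertion-point descriptors (CASimAM → backbone,
DRAMiTransformer → P3 head branch after the layer-15 C2f, MHSA-C2f → before
the detection head) are exported as YAML for a detector-framework model
file. Network assembly, training, and pretrained weights are out of scope.

## Numerical choices and problem sizes

* Depth maps are float64 in meters in memory; on disk 16-bit PNG
  millimeters (`depth_scale = 0.001`), which quantizes to ±0.5 mm.
* Rotation matrices are validated orthonormal with det +1 to 1e−9.
* The AP threshold comparison is strict (`>`), per the indicator
  definition; OKS threshold grids must be strictly increasing in (0, 1).
* Dataset split counts round half up per subset with the last subset taking
  the remainder, so sizes always sum to the total.
* Test and acceptance runs use 20 phantom geometries per condition and a
  10,000-draw OKS Monte Carlo; both were sized to give stable means (the
  calibrated jitter has fixed displacement magnitude, so its Monte-Carlo
  variance is zero up to direction-independent rounding) while keeping a
  full run on one CPU in tens of seconds.

## Known limitations

Single view only: no multi-view registration or non-rigid shape recovery.
The ground estimator assumes a level floor and enough visible floor near the
hooves; on sloped or cluttered floors the height traits degrade first. The
circular cross-section assumption biases cannon circumference on elliptical
limbs. The evaluation module implements the indicator form of AP; COCO-style
PR-curve AP values are not comparable to it.
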