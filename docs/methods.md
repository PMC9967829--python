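# Methods

This note documents the models and procedures implemented in `stairwatch`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that matter.

## Data model

A *session* is one person-present episode: strictly increasing timestamps
(nominal 15 Hz, gaps allowed), per-frame joint positions in millimetres, and
metadata labels (participant, up/down, carried object). Sessions where an
object was carried are excluded from analysis, since a held object changes
hand availability. Ingestion enforces two validity rules the downstream math
relies on: every stored joint is a finite 3-vector, and the three hand
joints of one side (HAND, HANDTIP, THUMB) are present all-or-nothing — a
partial triplet is treated as an untracked hand. Frames missing the pelvis
simply contribute nothing to speed; frames missing the analyzed hand
contribute nothing to grasp analysis. One tracked body per frame is assumed.

## Camera geometry

The ideal pinhole model with intrinsics `A = [[fx,0,cx],[0,fy,cy],[0,0,1]]`
is used in both directions: back-projection
`p = A⁻¹ (u·Pz, v·Pz, Pz)` of depth pixels, and perspective projection
`u = fx·X/Z + cx, v = fy·Y/Z + cy` for heat-map rendering. Lens distortion
is assumed to be removed upstream (depth SDKs deliver rectified maps).
Integer pixel coordinates denote pixel centers, which makes
`project ∘ back_project` an exact identity — a property the tests enforce at
1e−6 px.

## Stair frame

The wall plane is fit by **ordinary least squares in the depth direction**:
`[X, Y, 1]·[a b d]ᵀ = −Z`, normal seed `(a, b, 1)`. This is valid whenever
the wall is not edge-on to the camera (coefficient of Z nonzero), which
holds for any wall the camera can image as a region; no robust/RANSAC
variant is used because calibration clouds come from a hand-picked
rectangle. The residual reported is the Z-direction rms; multiplying by the
normal's Z component gives the plane-orthogonal rms.

Sign and orientation conventions, which the source geometry leaves open, are
fixed as follows and enforced by the generator:

- the wall normal is oriented **toward the camera** (non-negative dot
  product with the vector from the cloud centroid to the camera origin);
- the handrail start landmark is the **downhill** end, so stair-x increases
  up-slope and an ascending pelvis has increasing x;
- the basis is right-handed (`nz = nx × ny′`, `ny = nz × nx`). For
  installations where the resulting z-axis points up rather than down, the
  calibration file's `flip_lateral` flag negates the wall-normal seed, which
  flips z while preserving handedness and the x-axis.
- camera→stair mapping is `q = R(p − P0)`, i.e. `H = [R, −R·P0; 0 1]`,
  chosen so the handrail origin lands exactly on the stair-frame origin.

A near-parallel guard rejects bases where |nx·ny′| ≥ 0.99 (≈ 8° separation),
below which the cross products are numerically meaningless.

Landmarks (two handrail pixels, wall rectangle, origin pixel) live in a
JSON calibration file rather than an interactive picker, so a deployment's
frame is reproducible from its depth image.

## Traversal speed

Speed is the pelvis's **3-D path length / elapsed time** across the stair-x
window 0–1000 mm, entry and exit interpolated linearly onto the window
boundaries. Raw path length is upward-biased under per-frame skeleton noise
(at 15 Hz a 10 mm-σ jitter adds steps comparable to true 16 mm steps at
0.25 m/s), so the pelvis trajectory is smoothed first with a centered
moving average of 7 frames (~0.47 s). The filter is exact on
constant-velocity motion — a linear trajectory is its own moving average —
and reduces the noise-induced bias to ~2% at the slowest speeds of
interest; the two edge half-windows are discarded, which the generator's
±300 mm approach margins comfortably absorb. A `displacement` variant
(straight entry-to-exit chord / time) is available where a chord speed is
preferred; on straight paths the two coincide.

Direction is taken from the manual up/down label when present; otherwise it
is inferred from the sign of the net pelvis x-displacement, with traversals
under 100 mm net displacement rejected as indeterminate.

Group comparisons use **Welch's t-test** (two-sided): participant groups
have very unequal sizes and spreads, making the pooled-variance test
inappropriate. Two zero-variance samples with equal means yield p = 1 with
a warning instead of an error, a degenerate case synthetic fixtures hit.

## Grasp analysis

Grasp point: `Pgp = (Phand + Phandtip + Pthumb)/3` per hand. Which hand is
analyzed is configurable; the `auto` default picks the side with smaller
mean |stair-y|, i.e. the hand habitually nearer the handrail plane.
Analysis is restricted to the rail's straight part, the **open** interval
0 < Pgp_x < 1000 mm.

Classifier: binary CART, Gini impurity, max depth 4, minimum leaf 5 — small
trees matching the shallow decision boundaries this 2-D problem needs, and
deep enough to carve an axis-aligned box around the rail cross-section.
Evaluation is stratified 5-fold cross-validation with seeded shuffling; the
confusion matrix and accuracy come from held-out folds only, and the
deployed tree is then refit on all labeled data. Only manually labeled
frames ever enter training; the model is applied to all unlabeled
activities. The fitted tree is serialized as plain JSON node arrays and
prediction traverses those arrays, so saved models round-trip without
pickle.

Grasping ratio: grasped / total over straight-segment frames, per
participant × direction, reported with n.

Heat map: grasped-frame grasp points are inverse-transformed to camera
space, projected, binned at pixel resolution, and smoothed with a Gaussian
kernel (default σ = 15 px — a rendering choice sized to a handrail's image
width at ~2.5 m); the density is alpha-blended over the image with a jet
colormap, intensity ∝ frequency. Points behind the camera or outside the
image are skipped and counted.

## Synthetic generator

The generator defines the study conditions for all recovery tests:

- **Scene**: a planar wall tilted ~9° off frontal at ~2.4 m, a 1.8 m
  handrail of radius 20 mm mounted 60 mm in front of it, imaged by a
  640×576, f = 505 px depth camera; per-pixel Gaussian depth noise
  (default σ = 2 mm, typical of time-of-flight sensors at this range) plus
  1 mm quantization from 16-bit storage.
- **Traversals**: the pelvis moves along the slope (stair-x from −300 to
  1300 mm, bracketing the measurement window) at constant 3-D speed, offset
  350 mm laterally and 850 mm along stair-z from the rail axis; optional
  per-step oscillation is off by default since speed and grasp statistics
  do not depend on step discretization. During grasp episodes the hand
  triplet lies on the rail surface near the pelvis's x; otherwise it stays
  near the pelvis, >150 mm from the rail. Isotropic Gaussian joint noise
  (cohort default σ = 10 mm, a mid-range figure for consumer body
  tracking) is applied per joint per frame. All randomness derives from the
  per-call seed.
- **Cohort defaults**: six participants with per-direction mean speeds of
  0.54/0.60, 0.52/0.58, 0.50/0.68, 0.55/0.67, 0.24/0.39 and 0.37/0.24 m/s
  (up/down) and grasp fractions 4.6/3.8, 25/51, 2.5/8.7, 19/9.3, 81.6/48.2
  and 76.3/83.3 % — the speed and dependence contrasts of a mixed-age
  two-house deployment, with a 0.04 m/s between-traversal spread.
- **Labeled classifier fixtures**: grasped samples cluster at the rail
  cross-section center in (Pgp_y, Pgp_z) with 10 mm spread; not-grasped
  samples are offset along the direction a free-swinging hand actually
  occupies relative to the rail (toward the walker and below), default
  300 mm.

What the generator does **not** emulate: body-tracking failure modes other
than dropout and isotropic noise (no outlier limbs, identity switches or
multi-person frames), occlusion by the body, step-by-step gait dynamics,
and photorealistic appearance. Passing recovery tests therefore demonstrate
correctness of the geometry and statistics under idealized tracking, not
robustness to real tracker pathologies.

## Problem sizes

The test suite and acceptance script use desk-scale simulations chosen to
make the statistics stable: 10⁴ random pixels for projection identities;
100 random walls × 1000 points (σ = 5 mm) for plane-normal recovery; 100
traversals per speed at 0.25/0.5/0.75 m/s (σ = 10 mm) for speed recovery;
100 random traversals for direction inference; 1000 label-shuffled samples
for classifier chance bounds; and ~560 straight-segment frames across nine
slow traversals for the end-to-end grasp ratio. The whole suite runs in a
few seconds on one CPU.

## Known limitations

- The Z-direction least-squares plane fit is mildly biased for walls tilted
  far from frontal with isotropic noise; within the ±35° cone the
  calibration supports, the bias is far below the 1° acceptance band.
- Speed smoothing trades a small residual upward bias (~2% at 0.25 m/s with
  σ = 10 mm noise) for robustness; displacement speed is unbiased on
  straight paths but noisier on curved ones.
- The grasp classifier learns an environment-specific boundary; a model
  trained in one installation should not be applied to another without
  relabeling, exactly as separate trees were needed per house.
- Heat-map mass near the image border is truncated by the Gaussian kernel.
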