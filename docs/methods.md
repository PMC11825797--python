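# Methods

This note documents the models, conventions and numerical choices behind
`rownav`, and what its synthetic tests do and do not demonstrate about real
field data.

## Pinhole model and conventions

All geometry uses the ideal pinhole camera. Pixel coordinates are 0-based,
`(u, v) = (column, row)`, and an integer coordinate names a pixel *centre*.
The camera frame is X-right, Y-down, Z along the optical axis; **depth is
the Z coordinate**, not the Euclidean ray length. Lens distortion,
extrinsics and stereo rectification are out of scope.

Two intrinsics transforms matter for cross-camera work:

* resizing an image by `s` multiplies `fx, fy, cx, cy` by `s` (the
  pixel-represented focal length scales with the pixel grid);
* central cropping leaves `fx, fy` unchanged and shifts `cx, cy` by the
  crop offset.

Resized pixel dimensions are rounded to nearest; the intrinsics scale by the
*requested* factor, not the post-rounding ratio. The discrepancy is below
one pixel for any realistic factor and invisible at the tolerances used
anywhere in the package.

## Depth maps on disk

16-bit single-channel PNG, value = millimetres (`round(m × 1000)`), 0 =
missing, storage range 0–20 m. Nearest-integer rounding bounds the
round-trip error by 0.5 mm, and encode→decode→encode is bit-stable. On
decode, values above the declared range are treated as **missing rather than
clipped**: past its rated range a depth reading is noise, and for navigation
a dropped point is safer than a spurious far point. The same policy nulls
out-of-range values wherever the package constructs depth maps
(`DepthMap.sanitize`).

## Evaluation metrics

Eight masked scores (ABS-REL %, RMSE m, Silog, δ1/δ2/δ3 %, RMSElog,
SQ-REL), all computed on the identical mask: label non-null and inside the
evaluation range. Predictions are never masked on their own validity; a
null prediction under a valid label is an error for log metrics, not a
silently dropped pixel, because silent dropping would let a model improve
its score by predicting nothing where it is unsure.

Silog defaults to the variance form `mean(d²) − mean(d)²` with
`d = log(pred) − log(gt)` — the scale-invariant log error of the
Eigen/BinsFormer lineage, zero under any constant multiplicative bias. A
literal sum form (`+` between the terms) exists behind `form="sum"` for
comparison with sources that print it that way; it is not scale-invariant.
Numerically, the variance is computed two-pass (`mean((d − mean d)²)`) and
snapped to exactly 0 when it falls below the floating-point resolution of
`mean(d²)` (16 eps relative), so a constant-ratio prediction reports a clean
zero instead of a ~1e-16 residue.

The masked training loss is `alpha·sqrt(mean(d²) − lam·mean(d)²)` with
defaults `lam = 0.85`, `alpha = 10` — the standard weighting for silog
training on sparse labels. `lam = 1` degenerates to `alpha·std(d)`; a
negative radicand (possible only for `lam > 1`) is clamped to 0 with a
warning.

Dataset aggregation is the unweighted mean of per-image metrics, not pooled
pixels, so images with few valid labels count equally.

Chamfer distance is the squared symmetric convention:
`mean_A min_B ‖a−b‖² + mean_B min_A ‖a−b‖²` (k-d tree nearest neighbours);
an unsquared variant is available via `squared=False`. Units are therefore
m² in the default form.

## Fusion

Bands divide each instance's **own vertical extent**, not the full image:
scanline `r` of an instance spanning `[v_min, v_max]` belongs to band
`floor((r − v_min)·n_bands / extent)` (last band absorbs the remainder).
Per occupied band, the navigation point is the mean of all instance pixel
coordinates in that band. Per-instance banding was chosen over image-frame
banding because rows at different image extents should each contribute a
full complement of points along their visible length; the alternative is a
one-line change in `extract_navigation_points`.

Depth lookup at the (fractional) navigation point is nearest-pixel by
default. Bilinear interpolation is offered but not default: it blends
across the 0-missing sentinel, so a point next to a dropout hole would get
a fabricated depth (the implementation returns missing if any of the four
neighbours is null).

The 5 m depth filter is applied to the **label** depth when a label map is
supplied and to the prediction otherwise (deployment mode). Filtering on
the label makes predicted and label navigation points position-matched
pairs — same (u, v), same count — so their chamfer distance measures pure
depth error, not detection differences. If the prediction is null at a
label-kept position the pair is dropped from both sides and counted in the
result's warnings.

The navigation line is the ordered point sequence per instance; no fitting
or smoothing is applied. Row point clouds back-project every instance pixel
whose (label-)depth is valid and ≤ 5 m; an instance with no such pixel
yields an empty, warned-about cloud. The row-cloud chamfer distance of an
image is the mean over instances with non-empty clouds on both sides.

## Camera-migration calibration

The observed failure mode when a depth network trained on camera A runs on
camera B is a near-multiplicative depth bias governed by the ratio of
pixel-represented focal lengths. Both corrections invert it:

* **output scale**: divide predicted depths by `k`; grid 0.25–4.0, step 0.01;
* **input resize**: run the provider on the `s`-resized image and map the
  prediction back to label resolution with order-0 (value-preserving)
  resampling; grid 0.5–4.0, step 0.02.

The objective (default ABS-REL, range 0–5 m — the navigation-relevant band,
where depth labels are also most reliable) is averaged over the calibration
pairs and minimised by explicit grid sweep; ties break toward the smaller
factor. A grid rather than a continuous optimiser keeps the result exactly
reproducible and makes mis-set bounds visible in the returned score curve.
During the output-scale sweep the rescaled values are scored without the
storage-range cap so the score curve stays continuous in `k`; *applying* a
correction re-imposes the cap.

The ideal synthetic provider implements `pred = true · f_ref / (s · f_cam)`,
the simplest law consistent with the observed focal-length sensitivity, so
on it the two calibrations agree to grid resolution. On a real network the
two optima need not coincide (learned priors are not exactly multiplicative
in focal length); the package reports both and does not model the
discrepancy.

## Synthetic scenes

The generator emulates a depth camera at height `h` (default 1 m) pitched
`pitch` (default 0.35 rad ≈ 20°) toward a flat ground plane, with `n_rows`
(4) parallel strips of width 0.35 m at 0.6 m spacing running along the
driving direction — the scale of a machine-mounted camera over crop rows.
Default imaging: 320×240, f = 300 px, principal point at the centre. Depth
is closed-form ray/plane intersection; rays at or above the horizon, or
hitting beyond 20 m, are null, mimicking sky dropout.

Corruption is multiplicative lognormal noise (depth-camera error grows with
range; depth stays positive) followed by spatially uniform dropout, both
seeded. Defaults used in the shipped experiments: σ = 0.02 (≈1.6% ABS-REL
noise floor, the order of a good depth sensor in its near range) and the
bias factor 1.94 for migration scenarios — a realistic focal-length ratio
between a wide and a standard webcam-class sensor.

What the synthetic scenes do **not** model: row height relief, occlusion,
vegetation texture, structured (edge-correlated) dropout, rolling-shutter
or registration artefacts, and any non-multiplicative component of a real
network's cross-camera error. Passing tests therefore demonstrate the
correctness of the geometry, metrics, fusion contracts and calibration
mechanics — not field performance of any particular depth network.

Ground-truth navigation points are computed inside the generator by an
independent scalar double loop (closed-form depths, explicit
back-projection), deliberately separate from the fusion code, so end-to-end
tests compare two implementations of the same geometry.

## Problem sizes and degenerate inputs

Tests and the acceptance script run on 320×240 scenes (≈68k valid pixels,
~50 navigation points), sizes at which every sweep and fusion completes in
seconds while leaving all contracts fully exercised. Degenerate inputs are
contracts, not crashes: empty masks fuse to an empty result with a warning;
an all-dropped point set or empty cloud raises only where a distance is
actually requested; metric evaluation with zero valid pixels raises with an
explicit message.
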