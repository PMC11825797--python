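# rownav

Monocular recognition and localization of crop rows for agricultural
navigation.

A vehicle that must follow crop rows — here, the rolled rice-stubble rows a
ratoon-rice righting machine straightens — needs the *metric* 3D position of
each row, not just its outline in the image. `rownav` implements a
model-fusion approach that gets there with a single RGB camera: an instance
segmentation model supplies one mask per row, a monocular depth-prediction
model supplies a dense metric depth map, and pinhole geometry fuses the two
into 3D navigation lines and per-row point clouds. The trained networks
themselves are out of scope; they are represented by a pluggable *depth
provider* interface plus a fully synthetic field-scene generator, so every
stage is testable on a laptop.

The package is aimed at people building or evaluating vision-based field
navigation: it provides the geometry, the file conventions, the evaluation
metrics and the cross-camera calibration as a tested library with a thin CLI.

## What it computes

**Fusion.** Each row instance's vertical pixel extent is split into
`n_bands` (default 14) equal-height horizontal bands; per occupied band the
mean pixel coordinate of the instance's pixels gives a navigation point
(u, v). Its depth Z is read from the depth map and back-projected through
the pinhole model

    u = fx·X/Z + cx,   v = fy·Y/Z + cy

to a camera-frame point (X, Y, Z). The ordered points of an instance form
its navigation line; back-projecting every masked pixel gives the row's
point cloud. Depth beyond 5 m is discarded — only the near field matters for
steering.

**Depth encoding.** Depth maps are 16-bit single-channel PNGs holding
millimetres (metres × 1000, rounded), 0 = missing, storage range 0–20 m.

**Metrics.** The eight standard masked depth scores (ABS-REL, RMSE, Silog,
δ1/δ2/δ3, RMSElog, SQ-REL), the masked silog training loss, and the
(squared, symmetric) chamfer distance between point clouds.

**Camera migration.** A depth network learns the pixel-represented focal
length of its training camera and mis-scales depth roughly multiplicatively
on any other camera. Two grid-searched corrections invert the bias: resize
the input image by a factor *s* before inference, or divide the predicted
depths by a constant *k*. Both are calibrated against a small set of depth
labels by minimising ABS-REL on the 0–5 m range.

## Worked example

Simulate a camera migration with a 1.94× focal-length bias plus 2%
multiplicative depth noise, calibrate it away, and fuse:

```python
from rownav import (SceneConfig, CorruptionConfig, render_scene, biased_provider,
                    calibrate_output_scale, apply_correction, DepthPair, evaluate, fuse)

scene = render_scene(SceneConfig(seed=0))
provider = biased_provider(scene.config, f_ref_over_f_cam=1.94,
                           noise=CorruptionConfig(noise_sigma=0.02, seed=0))
pred = provider(None, 1.0)
print("uncorrected:", evaluate(DepthPair.from_maps(pred, scene.depth, (0, 5))).format_row())

cal = calibrate_output_scale(provider, [(None, scene.depth)])
print(f"recovered output scale: {cal.factor:.2f}")
corrected = apply_correction(pred, cal)
print("corrected:  ", evaluate(DepthPair.from_maps(corrected, scene.depth, (0, 5))).format_row())

result = fuse(scene.masks, corrected, scene.config.camera, depth_label=scene.depth)
print(f"navigation points: {len(result.pred_points)}, "
      f"CD(nav) = {result.cd_navigation:.4f}, CD(rows) = {result.cd_rows:.4f}")
```

Output:

```
uncorrected: ABS-REL   94.0%  RMSE  2.482  Silog  0.000  d1   0.0%  d2   0.0%  d3  63.3%  RMSElog  0.663  SQ-REL  0.886
recovered output scale: 1.94
corrected:   ABS-REL    1.6%  RMSE  0.053  Silog  0.000  d1 100.0%  d2 100.0%  d3 100.0%  RMSElog  0.020  SQ-REL  0.000
navigation points: 48, CD(nav) = 0.0083, CD(rows) = 0.0006
```

Reading it: the migrated model is useless out of the box (94% relative
error, no pixel within the δ1 ratio band) yet its *Silog is zero* — the
error is a pure global scale, which is exactly what the scale-invariant log
metric ignores and what the calibration removes. The grid search recovers
the constructed 1.94 bias; after division the depth error collapses to the
noise floor (≈1.6% = E|e^{0.02·Z} − 1|·100), and the fused 3D navigation
points land within millimetres of the sensor-label points (chamfer distances
in m²).

The same pipeline from the shell:

```sh
rownav simulate --out fixtures --seed 7 --bias-factor 1.94 --noise-sigma 0.02
rownav calibrate --dir fixtures --out cal.json --factor 1.94 --noise-sigma 0.02
rownav fuse --dir fixtures --out fused
rownav evaluate --dir fixtures --out report.json --range 0 5
```

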