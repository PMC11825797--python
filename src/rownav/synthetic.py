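"""Synthetic field scenes: analytic depth, row masks, sensor corruption, biased providers.

The generator emulates the data a forward-tilted depth camera sees over a
harvested paddy field: a flat ground plane a fixed height below the camera,
with parallel row strips (the crop rows a vehicle must follow) running away
from the camera.  Depth is rendered in closed form by intersecting each
pixel's viewing ray with the plane, so every downstream computation can be
checked against exact geometry — no trained network and no recorded data are
involved.

World frame: the camera sits at height ``h`` above the plane; its optical
axis is pitched *down* by ``pitch`` radians from horizontal.  For pixel
``(u, v)`` the ray direction in the camera frame is
``((u-cx)/fx, (v-cy)/fy, 1)``; the depth (camera-frame Z) of its ground
intersection is

    Z(u, v) = h * fy / (fy * sin(pitch) + (v - cy) * cos(pitch))

Pixels whose ray never meets the plane (at or above the horizon) or meets it
beyond ``max_range`` carry the null value 0, mimicking the dropout regions a
real depth camera produces against the sky or at long range.

Two corruption stages make the fixtures sensor-like: multiplicative
lognormal noise (depth-camera error grows with range and depth is positive)
and uniform random dropout.  A *biased provider* stands in for a monocular
depth network whose training camera had a different pixel-represented focal
length than the deployment camera: its prediction at input-resize factor
``s`` equals ``true_depth * f_ref_over_f_cam / s`` — the minimal model of
the focal-length sensitivity that the input-resize / output-scale
calibrations correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .depth_io import DepthMap
from .fusion import InstanceMaskSet, NavigationPoint
from .geometry import CameraIntrinsics, intrinsics_after_resize

__all__ = [
    "SceneConfig",
    "CorruptionConfig",
    "Scene",
    "render_scene",
    "corrupt",
    "biased_provider",
    "placeholder_rgb",
]


def _default_camera() -> CameraIntrinsics:
    return CameraIntrinsics(fx=300.0, fy=300.0, cx=160.0, cy=120.0, width=320, height=240)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of a synthetic field scene.

    Defaults give a camera ~1 m above the ground pitched ~20 degrees down,
    four rows 0.6 m apart and 0.35 m wide — the scale of machine-mounted
    cameras looking at crop rows.
    """

    camera: CameraIntrinsics = field(default_factory=_default_camera)
    camera_height: float = 1.0  # m above the ground plane
    pitch: float = 0.35  # rad, downward tilt of the optical axis
    n_rows: int = 4
    row_spacing: float = 0.6  # m between row centrelines
    row_width: float = 0.35  # m, strip width (< spacing)
    row_length: float = 10.0  # m along the driving direction
    row_start: float = 0.5  # m, forward distance where strips begin
    max_range: float = 20.0  # m, sensor storage range
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.camera_height > 0:
            raise ValueError(f"camera_height must be > 0, got {self.camera_height}")
        if not 0 < self.pitch < np.pi / 2:
            raise ValueError(f"pitch must be in (0, pi/2), got {self.pitch}")
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be >= 1, got {self.n_rows}")
        if not self.row_spacing > self.row_width > 0:
            raise ValueError(
                f"need row_spacing > row_width > 0, got {self.row_spacing}, {self.row_width}"
            )


@dataclass(frozen=True)
class CorruptionConfig:
    """Sensor-corruption model: dropout fraction and lognormal noise sigma."""

    dropout_rate: float = 0.0
    noise_sigma: float = 0.0
    max_range: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def ground_depth(cfg: SceneConfig, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Closed-form ground-plane depth at (possibly fractional) pixels.

    Returns 0 where the ray misses the plane or the hit is beyond max_range.
    """
    k = cfg.camera
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    denom = np.sin(cfg.pitch) + (v - k.cy) / k.fy * np.cos(cfg.pitch)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, cfg.camera_height / denom, 0.0)
    return np.where((t > 0) & (t <= cfg.max_range), t, 0.0)


def _ground_xz(cfg: SceneConfig, u: np.ndarray, v: np.ndarray, t: np.ndarray):
    """World (x, z) of the ground hit: x across rows, z forward along them."""
    k = cfg.camera
    x = t * (u - k.cx) / k.fx
    z = t * (np.cos(cfg.pitch) - np.sin(cfg.pitch) * (v - k.cy) / k.fy)
    return x, z


def row_centers(cfg: SceneConfig) -> np.ndarray:
    """Across-track centreline positions of the rows, centred on the camera."""
    return (np.arange(cfg.n_rows) - (cfg.n_rows - 1) / 2) * cfg.row_spacing


@dataclass
class Scene:
    """A rendered scene: depth label, instance masks, analytic navigation truth."""

    depth: DepthMap
    masks: InstanceMaskSet
    nav_points: list[NavigationPoint]
    config: SceneConfig


def render_scene(cfg: SceneConfig, n_bands: int = 14) -> Scene:
    """Render the label depth map, the per-row instance masks and ground truth.

    Ground-truth navigation points are computed here by an explicit per-band
    loop over mask scanlines with closed-form depths — deliberately separate
    code from the fusion pipeline, so end-to-end tests compare two
    independent routes to the same geometry.
    """
    k = cfg.camera
    vv, uu = np.mgrid[0 : k.height, 0 : k.width].astype(float)
    t = ground_depth(cfg, uu, vv)
    if not np.any(t > 0):
        raise ValueError(
            f"pitch={cfg.pitch} rad: no ray reaches the ground within "
            f"max_range={cfg.max_range} m"
        )
    x, z = _ground_xz(cfg, uu, vv, t)
    labels = np.zeros(t.shape, dtype=np.int32)
    for i, c in enumerate(row_centers(cfg), start=1):
        inside = (
            (t > 0)
            & (np.abs(x - c) <= cfg.row_width / 2)
            & (z >= cfg.row_start)
            & (z <= cfg.row_start + cfg.row_length)
        )
        labels[inside] = i

    depth = DepthMap(t, max_range=cfg.max_range)
    masks = InstanceMaskSet(labels)
    nav = _analytic_nav_points(cfg, labels, n_bands)
    return Scene(depth=depth, masks=masks, nav_points=nav, config=cfg)


def _analytic_nav_points(
    cfg: SceneConfig, labels: np.ndarray, n_bands: int
) -> list[NavigationPoint]:
    # Scalar double loop, closed-form depth, explicit back-projection:
    # the independent route used as ground truth for end-to-end checks.
    k = cfg.camera
    points: list[NavigationPoint] = []
    for inst in sorted(int(i) for i in np.unique(labels) if i != 0):
        rows = [r for r in range(labels.shape[0]) if np.any(labels[r] == inst)]
        v_min, v_max = rows[0], rows[-1]
        extent = v_max - v_min + 1
        band_u: dict[int, list[int]] = {}
        band_v: dict[int, list[int]] = {}
        for r in rows:
            b = min((r - v_min) * n_bands // extent, n_bands - 1)
            cols = np.nonzero(labels[r] == inst)[0]
            band_u.setdefault(b, []).extend(int(c) for c in cols)
            band_v.setdefault(b, []).extend([r] * len(cols))
        for b in sorted(band_u):
            u = float(np.mean(band_u[b]))
            v = float(np.mean(band_v[b]))
            d = float(ground_depth(cfg, round(u), round(v)))
            if d <= 0:
                continue
            p3 = np.array([(u - k.cx) * d / k.fx, (v - k.cy) * d / k.fy, d])
            points.append(NavigationPoint(inst, b, u, v, depth=d, point3d=p3))
    return points


def corrupt(depth: DepthMap, c: CorruptionConfig) -> DepthMap:
    """Apply multiplicative lognormal noise then uniform dropout; seeded.

    Null pixels stay null; noised values above ``c.max_range`` become null
    (the encoder's out-of-range policy).
    """
    rng = np.random.default_rng(c.seed)
    v = depth.values.copy()
    valid = v > 0
    if c.noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=c.noise_sigma, size=v.shape)
        v[valid] *= noise[valid]
    if c.dropout_rate > 0:
        drop = rng.random(v.shape) < c.dropout_rate
        v[drop] = 0.0
    return DepthMap.sanitize(v, max_range=c.max_range)


def biased_provider(
    cfg: SceneConfig,
    f_ref_over_f_cam: float = 1.0,
    noise: CorruptionConfig | None = None,
) -> Callable[..., DepthMap]:
    """A depth-provider stand-in with controllable focal-length bias.

    The returned callable has the provider contract
    ``provider(image, scale=1.0) -> DepthMap`` at the ``scale``-resized
    resolution.  It ignores the pixel content of ``image`` — the scene
    configuration plays the role of the visual input — and predicts

        ``true_depth(at resized intrinsics) * f_ref_over_f_cam / scale``

    i.e. a network trained at reference focal length ``f_ref`` systematically
    mis-scales depth by ``f_ref / (s * f_cam)`` when run on this camera's
    images resized by ``s``.  At ``scale = f_ref_over_f_cam`` the bias
    cancels — the mechanism input-resize calibration exploits.  Optional
    corruption is re-seeded deterministically per scale so the provider is a
    pure function of (input, scale).
    """
    if not f_ref_over_f_cam > 0:
        raise ValueError(f"f_ref_over_f_cam must be > 0, got {f_ref_over_f_cam}")

    def provider(image=None, scale: float = 1.0) -> DepthMap:
        k_s = intrinsics_after_resize(cfg.camera, scale)
        cfg_s = replace(cfg, camera=k_s)
        vv, uu = np.mgrid[0 : k_s.height, 0 : k_s.width].astype(float)
        t = ground_depth(cfg_s, uu, vv)
        pred = np.where(t > 0, t * f_ref_over_f_cam / scale, 0.0)
        d = DepthMap.sanitize(pred, max_range=cfg.max_range)
        if noise is not None and (noise.noise_sigma > 0 or noise.dropout_rate > 0):
            d = corrupt(d, replace(noise, seed=noise.seed + int(round(scale * 1000))))
        return d

    return provider


def placeholder_rgb(cfg: SceneConfig) -> np.ndarray:
    """A simple shaded RGB rendering of the scene (uint8), for fixture files."""
    scene_depth = render_scene(cfg, n_bands=1)
    t = scene_depth.depth.values
    lab = scene_depth.masks.labels
    img = np.zeros(t.shape + (3,), dtype=np.uint8)
    ground = t > 0
    shade = np.zeros_like(t)
    shade[ground] = np.clip(1.0 - t[ground] / cfg.max_range, 0.0, 1.0)
    img[..., 0] = (120 * shade).astype(np.uint8)
    img[..., 1] = (90 * shade).astype(np.uint8)
    img[..., 2] = (60 * shade).astype(np.uint8)
    img[~ground] = (160, 190, 230)  # sky
    rng = np.random.default_rng(cfg.seed)
    hues = rng.integers(80, 255, size=(int(lab.max(initial=0)) + 1, 3), dtype=np.int64)
    rows = lab > 0
    img[rows] = hues[lab[rows]]
    return img
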