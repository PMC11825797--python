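"""Fusing instance masks with a depth map into navigation lines and row clouds.

The localization method: an instance-segmentation model outputs one mask per
crop row; a monocular depth model outputs a dense metric depth map for the
same image.  Each instance's vertical pixel extent is split into ``n_bands``
equal-height horizontal bands and, per occupied band, the mean pixel
coordinate of the instance's pixels gives one 2D navigation point.  Looking
those points up in the depth map and back-projecting through the camera
intrinsics yields the 3D navigation line the vehicle follows; back-projecting
every masked pixel yields a per-row point cloud.

Depth beyond ``max_depth`` (default 5 m) is discarded: only the near field
matters for steering and depth-camera labels degrade with range.  When a
label (sensor) depth map accompanies the prediction, the filter is applied on
the *label* depth so that predicted and label points form position-matched
pairs at identical ``(u, v)``, which is what makes their chamfer distance a
pure depth-error measure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depth_io import DepthMap
from .geometry import CameraIntrinsics, backproject
from .metrics import chamfer_distance

__all__ = [
    "InstanceMaskSet",
    "FusionConfig",
    "NavigationPoint",
    "FusionResult",
    "extract_navigation_points",
    "attach_depth",
    "to_camera_frame",
    "row_point_cloud",
    "fuse",
]

logger = logging.getLogger(__name__)


@dataclass
class InstanceMaskSet:
    """Integer label image: 0 = background, k = the k-th row instance."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"label image must be 2D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError(f"label image must be integer, got dtype {lab.dtype}")
        if np.any(lab < 0):
            raise ValueError("negative instance labels")
        self.labels = lab

    @property
    def instance_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class FusionConfig:
    """Knobs of the fusion step.

    n_bands : horizontal bands each instance is divided into (14 matches the
        row geometry this method was developed for).
    max_depth : navigation depth cutoff in metres; points and cloud pixels
        beyond it are dropped.
    depth_lookup : ``"nearest"`` reads the depth of the pixel nearest to the
        fractional navigation point; ``"bilinear"`` interpolates the four
        neighbours but blends across the 0-missing sentinel, so nearest is
        the default.
    """

    n_bands: int = 14
    max_depth: float = 5.0
    depth_lookup: str = "nearest"

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError(f"n_bands must be >= 1, got {self.n_bands}")
        if not self.max_depth > 0:
            raise ValueError(f"max_depth must be > 0, got {self.max_depth}")
        if self.depth_lookup not in ("nearest", "bilinear"):
            raise ValueError(f"unknown depth_lookup {self.depth_lookup!r}")


@dataclass
class NavigationPoint:
    """One band centroid of one row instance, optionally lifted to 3D."""

    instance_id: int
    band_index: int
    u: float
    v: float
    depth: float | None = None
    point3d: np.ndarray | None = None

    def to_record(self) -> dict:
        rec = {
            "instance_id": self.instance_id,
            "band": self.band_index,
            "u": self.u,
            "v": self.v,
            "depth": self.depth,
        }
        if self.point3d is not None:
            rec.update(x=float(self.point3d[0]), y=float(self.point3d[1]),
                       z=float(self.point3d[2]))
        return rec


def extract_navigation_points(
    masks: InstanceMaskSet, cfg: FusionConfig = FusionConfig()
) -> list[NavigationPoint]:
    """Per-instance band centroids in image coordinates (the 2D stage).

    Each instance's own vertical extent ``[v_min, v_max]`` is partitioned into
    ``n_bands`` equal-height bands; scanline ``r`` belongs to band
    ``floor((r - v_min) * n_bands / extent)``.  A band with no instance pixels
    emits no point (short instances yield fewer than ``n_bands`` points).
    Points are ordered by instance id, then band from image top down — the
    ordered sequence per instance is the navigation line.
    """
    points: list[NavigationPoint] = []
    lab = masks.labels
    for inst in masks.instance_ids:
        vs, us = np.nonzero(lab == inst)
        if vs.size == 0:  # instance_ids guarantees nonzero, but be explicit
            raise ValueError(f"instance {inst} has no pixels")
        v_min, v_max = int(vs.min()), int(vs.max())
        extent = v_max - v_min + 1
        bands = np.minimum((vs - v_min) * cfg.n_bands // extent, cfg.n_bands - 1)
        for b in range(cfg.n_bands):
            sel = bands == b
            if not np.any(sel):
                continue
            points.append(
                NavigationPoint(
                    instance_id=inst,
                    band_index=b,
                    u=float(np.mean(us[sel])),
                    v=float(np.mean(vs[sel])),
                )
            )
    return points


def _lookup(depth: DepthMap, u: float, v: float, mode: str) -> float:
    h, w = depth.values.shape
    if mode == "nearest":
        ui = min(max(int(round(u)), 0), w - 1)
        vi = min(max(int(round(v)), 0), h - 1)
        return float(depth.values[vi, ui])
    # bilinear over the four neighbours; a 0 neighbour poisons the blend,
    # so return missing if any corner is null
    u0 = min(max(int(np.floor(u)), 0), w - 1)
    v0 = min(max(int(np.floor(v)), 0), h - 1)
    u1, v1 = min(u0 + 1, w - 1), min(v0 + 1, h - 1)
    corners = depth.values[[v0, v0, v1, v1], [u0, u1, u0, u1]]
    if np.any(corners == 0):
        return 0.0
    fu, fv = u - u0, v - v0
    top = corners[0] * (1 - fu) + corners[1] * fu
    bot = corners[2] * (1 - fu) + corners[3] * fu
    return float(top * (1 - fv) + bot * fv)


def attach_depth(
    points: list[NavigationPoint],
    depth: DepthMap,
    cfg: FusionConfig = FusionConfig(),
    filter_depth: DepthMap | None = None,
) -> list[NavigationPoint]:
    """Look up each point's depth and drop points failing the depth filter.

    The filter (missing, or beyond ``cfg.max_depth``) is evaluated on
    ``filter_depth`` when given — e.g. the label map, so predicted and label
    point sets stay position-matched — and on ``depth`` itself otherwise.
    Returns new points; the input list is not modified.
    """
    if filter_depth is not None and filter_depth.values.shape != depth.values.shape:
        raise ValueError("filter_depth shape differs from depth shape")
    out: list[NavigationPoint] = []
    for p in points:
        d = _lookup(depth, p.u, p.v, cfg.depth_lookup)
        d_filt = d if filter_depth is None else _lookup(filter_depth, p.u, p.v, cfg.depth_lookup)
        if d_filt <= 0 or d_filt > cfg.max_depth or d <= 0:
            continue
        out.append(NavigationPoint(p.instance_id, p.band_index, p.u, p.v, depth=d))
    return out


def to_camera_frame(
    points: list[NavigationPoint], k: CameraIntrinsics
) -> list[NavigationPoint]:
    """Back-project points carrying depth into the camera frame (metres)."""
    out: list[NavigationPoint] = []
    for p in points:
        if p.depth is None:
            raise ValueError(
                f"navigation point (instance {p.instance_id}, band {p.band_index}) "
                "has no depth; run attach_depth first"
            )
        xyz = backproject(p.u, p.v, p.depth, k)
        out.append(NavigationPoint(p.instance_id, p.band_index, p.u, p.v,
                                   depth=p.depth, point3d=np.asarray(xyz, float)))
    return out


def row_point_cloud(
    masks: InstanceMaskSet,
    depth: DepthMap,
    k: CameraIntrinsics,
    cfg: FusionConfig = FusionConfig(),
    filter_depth: DepthMap | None = None,
) -> dict[int, np.ndarray]:
    """Back-project every masked pixel with usable depth, per instance.

    Returns ``{instance_id: (N, 3) array}``; an instance whose pixels all
    fail the depth filter maps to an empty ``(0, 3)`` array (and a warning is
    logged).  ``filter_depth`` plays the same role as in :func:`attach_depth`.
    """
    if masks.shape != depth.values.shape:
        raise ValueError(f"mask shape {masks.shape} != depth shape {depth.values.shape}")
    filt = filter_depth.values if filter_depth is not None else depth.values
    usable = (filt > 0) & (filt <= cfg.max_depth) & (depth.values > 0)
    clouds: dict[int, np.ndarray] = {}
    for inst in masks.instance_ids:
        sel = (masks.labels == inst) & usable
        vs, us = np.nonzero(sel)
        if vs.size == 0:
            logger.warning("instance %d has no valid-depth pixels; empty cloud", inst)
            clouds[inst] = np.empty((0, 3), dtype=float)
            continue
        clouds[inst] = backproject(us.astype(float), vs.astype(float),
                                   depth.values[vs, us], k)
    return clouds


@dataclass
class FusionResult:
    """Everything the fusion pipeline produces for one image."""

    pred_points: list[NavigationPoint]
    pred_clouds: dict[int, np.ndarray]
    label_points: list[NavigationPoint] | None = None
    label_clouds: dict[int, np.ndarray] | None = None
    cd_navigation: float | None = None
    cd_rows: float | None = None
    warnings: list[str] = field(default_factory=list)

    def points_to_json(self, path: str | Path, which: str = "pred") -> None:
        pts = self.pred_points if which == "pred" else (self.label_points or [])
        Path(path).write_text(
            json.dumps([p.to_record() for p in pts], indent=2) + "\n"
        )


def _points_array(points: list[NavigationPoint]) -> np.ndarray:
    if not points:
        return np.empty((0, 3), dtype=float)
    return np.stack([p.point3d for p in points])


def fuse(
    masks: InstanceMaskSet,
    depth_pred: DepthMap,
    k: CameraIntrinsics,
    depth_label: DepthMap | None = None,
    cfg: FusionConfig = FusionConfig(),
) -> FusionResult:
    """Run the full pipeline: 2D points -> depth -> 3D lines + row clouds.

    With a label depth map the same (u, v) positions are also looked up in the
    label, the 5 m filter is taken from the label, and the two chamfer
    distances are reported: over pooled 3D navigation points, and the mean of
    per-instance row-cloud chamfer distances.
    """
    if masks.shape != depth_pred.values.shape:
        raise ValueError(f"mask shape {masks.shape} != depth shape {depth_pred.values.shape}")
    result_warnings: list[str] = []
    pts2d = extract_navigation_points(masks, cfg)
    if not pts2d:
        result_warnings.append("no instances in mask; empty fusion result")
        logger.warning(result_warnings[-1])
        return FusionResult(pred_points=[], pred_clouds={}, warnings=result_warnings)

    if depth_label is None:
        pred_pts = to_camera_frame(attach_depth(pts2d, depth_pred, cfg), k)
        clouds = row_point_cloud(masks, depth_pred, k, cfg)
        return FusionResult(pred_points=pred_pts, pred_clouds=clouds,
                            warnings=result_warnings)

    # label-filtered, position-matched mode
    label_pts = attach_depth(pts2d, depth_label, cfg)
    pred_pts = attach_depth(
        [NavigationPoint(p.instance_id, p.band_index, p.u, p.v) for p in label_pts],
        depth_pred, cfg, filter_depth=depth_label,
    )
    if len(pred_pts) != len(label_pts):
        # prediction null at a label-kept position: drop the pair on both sides
        kept = {(p.instance_id, p.band_index) for p in pred_pts}
        dropped = len(label_pts) - len(pred_pts)
        label_pts = [p for p in label_pts if (p.instance_id, p.band_index) in kept]
        result_warnings.append(
            f"{dropped} navigation point(s) dropped: prediction null at label position"
        )
    label_pts = to_camera_frame(label_pts, k)
    pred_pts = to_camera_frame(pred_pts, k)

    label_clouds = row_point_cloud(masks, depth_label, k, cfg)
    pred_clouds = row_point_cloud(masks, depth_pred, k, cfg, filter_depth=depth_label)
    # pair clouds on pixels where both maps are valid
    for inst in list(pred_clouds):
        if pred_clouds[inst].shape[0] != label_clouds[inst].shape[0]:
            sel = ((masks.labels == inst)
                   & (depth_label.values > 0)
                   & (depth_label.values <= cfg.max_depth)
                   & (depth_pred.values > 0))
            vs, us = np.nonzero(sel)
            label_clouds[inst] = backproject(us.astype(float), vs.astype(float),
                                             depth_label.values[vs, us], k) \
                if vs.size else np.empty((0, 3))

    cd_nav = None
    a, b = _points_array(pred_pts), _points_array(label_pts)
    if a.shape[0] and b.shape[0]:
        cd_nav = chamfer_distance(a, b)
    else:
        result_warnings.append("no navigation points survived the depth filter")

    per_row = [
        chamfer_distance(pred_clouds[i], label_clouds[i])
        for i in pred_clouds
        if pred_clouds[i].shape[0] and label_clouds[i].shape[0]
    ]
    cd_rows = float(np.mean(per_row)) if per_row else None
    if cd_rows is None:
        result_warnings.append("no row cloud had valid pixels on both maps")
    for w in result_warnings:
        logger.warning(w)
    return FusionResult(
        pred_points=pred_pts,
        pred_clouds=pred_clouds,
        label_points=label_pts,
        label_clouds=label_clouds,
        cd_navigation=cd_nav,
        cd_rows=cd_rows,
        warnings=result_warnings,
    )


def write_xyz(cloud: np.ndarray, path: str | Path) -> None:
    """ASCII XYZ export: one ``x y z`` line per point, metres."""
    np.savetxt(Path(path), np.atleast_2d(cloud), fmt="%.6f")


def write_ply(cloud: np.ndarray, path: str | Path) -> None:
    """Minimal ASCII PLY export."""
    cloud = np.atleast_2d(cloud)
    header = (
        "ply\nformat ascii 1.0\n"
        f"element vertex {cloud.shape[0]}\n"
        "property float x\nproperty float y\nproperty float z\nend_header\n"
    )
    body = "\n".join(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in cloud)
    Path(path).write_text(header + body + ("\n" if cloud.shape[0] else ""))
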