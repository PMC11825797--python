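"""Pinhole camera geometry: projection, back-projection and intrinsics transforms.

Conventions
-----------
* Pixel coordinates are 0-based, ``(u, v) = (column, row)``; an integer
  coordinate refers to the centre of a pixel.
* The camera frame has X to the right, Y down and Z along the optical axis.
  "Depth" always means the Z coordinate of a point (its distance along the
  optical axis), not the Euclidean length of the viewing ray.
* Focal lengths and optical centre are pixel-represented: ``fx, fy`` are the
  physical focal length divided by the pixel pitch.  Resizing an image scales
  them; cropping does not.

The projection model is the standard pinhole relation

.. math::

    u = f_x \\, X/Z + c_x, \\qquad v = f_y \\, Y/Z + c_y, \\qquad Z = \\text{depth}

with the inverse ``X = (u - c_x) Z / f_x``, ``Y = (v - c_y) Z / f_y``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "project",
    "backproject",
    "intrinsics_after_resize",
    "intrinsics_after_center_crop",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics plus the image size they refer to.

    Parameters
    ----------
    fx, fy :
        Pixel-represented focal lengths (px), strictly positive.
    cx, cy :
        Optical centre (px), inside the image.
    width, height :
        Image size in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image size must be >= 1 px, got {self.width}x{self.height}")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError(
                f"optical centre ({self.cx}, {self.cy}) outside image {self.width}x{self.height}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(height, width)`` of images taken with these intrinsics."""
        return (self.height, self.width)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraIntrinsics":
        d = json.loads(Path(path).read_text())
        return cls(
            fx=float(d["fx"]), fy=float(d["fy"]),
            cx=float(d["cx"]), cy=float(d["cy"]),
            width=int(d["width"]), height=int(d["height"]),
        )


def project(points: np.ndarray, k: CameraIntrinsics) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project camera-frame 3D points to pixel coordinates.

    Parameters
    ----------
    points :
        Array of shape ``(..., 3)`` holding ``(X, Y, Z)`` in metres.
    k :
        Camera intrinsics.

    Returns
    -------
    u, v, depth :
        Pixel coordinates (possibly fractional) and the depth ``Z`` of each
        point, all with shape ``points.shape[:-1]``.

    Raises
    ------
    ValueError
        If any point has ``Z <= 0`` (behind or on the camera plane).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) points, got shape {pts.shape}")
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    if not np.all(np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("cannot project points with non-positive depth (behind the camera)")
    u = k.fx * x / z + k.cx
    v = k.fy * y / z + k.cy
    return u, v, z.copy()


def backproject(
    u: np.ndarray, v: np.ndarray, depth: np.ndarray, k: CameraIntrinsics
) -> np.ndarray:
    """Lift pixel coordinates with known depth to camera-frame 3D points.

    Exact inverse of :func:`project`.  ``u``, ``v`` and ``depth`` broadcast
    against each other; the result has shape ``broadcast(...) + (3,)``.

    Raises
    ------
    ValueError
        If any depth is non-positive or non-finite.  A depth of 0 encodes a
        missing measurement and must be filtered out before back-projection.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if not np.all(np.isfinite(depth)) or np.any(depth <= 0):
        raise ValueError("depth must be finite and > 0 (0 encodes a missing measurement)")
    u, v, depth = np.broadcast_arrays(u, v, depth)
    x = (u - k.cx) * depth / k.fx
    y = (v - k.cy) * depth / k.fy
    return np.stack([x, y, np.asarray(depth, dtype=float)], axis=-1)


def intrinsics_after_resize(k: CameraIntrinsics, s: float) -> CameraIntrinsics:
    """Intrinsics of the same camera after resizing the image by factor ``s``.

    Resizing scales the pixel-represented focal length and the optical centre
    by ``s``; the new image size is rounded to the nearest pixel while the
    intrinsics scale by the requested ``s`` (the sub-pixel discrepancy from
    rounding is negligible for any realistic factor).
    """
    if not (np.isfinite(s) and s > 0):
        raise ValueError(f"resize factor must be > 0, got {s}")
    return CameraIntrinsics(
        fx=k.fx * s,
        fy=k.fy * s,
        cx=k.cx * s,
        cy=k.cy * s,
        width=max(1, int(round(k.width * s))),
        height=max(1, int(round(k.height * s))),
    )


def intrinsics_after_center_crop(
    k: CameraIntrinsics, new_width: int, new_height: int
) -> CameraIntrinsics:
    """Intrinsics after a central crop to ``new_width`` x ``new_height``.

    Cropping leaves the pixel-represented focal length unchanged and shifts
    the optical centre by the crop offset.
    """
    if not (0 < new_width <= k.width and 0 < new_height <= k.height):
        raise ValueError(
            f"crop {new_width}x{new_height} must be within the image {k.width}x{k.height}"
        )
    return CameraIntrinsics(
        fx=k.fx,
        fy=k.fy,
        cx=k.cx - (k.width - new_width) / 2,
        cy=k.cy - (k.height - new_height) / 2,
        width=int(new_width),
        height=int(new_height),
    )
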