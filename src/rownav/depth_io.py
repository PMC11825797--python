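"""Metric depth maps and their on-disk 16-bit millimetre PNG encoding.

Depth is stored as a single-channel 16-bit PNG whose integer values are
millimetres: metres are multiplied by 1000 and rounded, which keeps three
decimals of precision (<= 0.5 mm quantisation error).  The value 0 is a
sentinel for "no measurement" — depth cameras return null where stereo
matching or the IR projector fails — and every consumer in this package
treats 0 as missing, never as a distance.

Instance masks ride along as 8/16-bit label PNGs (0 = background, n = the
n-th row instance).  Files are paired by shared stem::

    scene.png  scene_depth.png  scene_mask.png
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DepthMap",
    "DepthFormatError",
    "encode_depth_png",
    "decode_depth_png",
    "read_mask_png",
    "write_mask_png",
    "find_pairs",
]

#: Storage range of the depth encoding, metres.
DEFAULT_MAX_RANGE = 20.0

_DEPTH_MODES = ("I;16", "I;16B", "I;16L", "I")  # PIL modes a 16-bit grey PNG may decode to


class DepthFormatError(ValueError):
    """A depth PNG does not follow the 16-bit single-channel convention."""


@dataclass
class DepthMap:
    """A metric depth grid with the 0-as-missing convention.

    Attributes
    ----------
    values :
        2D float array of depths in metres; ``0`` marks missing pixels.
    max_range :
        Largest representable depth (m).  Values above it are not clipped but
        treated as missing — beyond the sensor's stated range a reading is
        noise, and for navigation a spurious "far" reading is safer dropped.
    """

    values: np.ndarray
    max_range: float = DEFAULT_MAX_RANGE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"depth map must be 2D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("depth map contains non-finite values")
        if np.any(v < 0):
            raise ValueError("depth map contains negative values")
        if np.any(v > self.max_range):
            raise ValueError(
                f"depth map exceeds max_range={self.max_range} m; "
                "use DepthMap.sanitize to null out-of-range values"
            )
        self.values = v

    @classmethod
    def sanitize(cls, values: np.ndarray, max_range: float = DEFAULT_MAX_RANGE) -> "DepthMap":
        """Build a DepthMap, nulling (-> 0) values above ``max_range``."""
        v = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("depth values must be finite")
        v = np.where(v > max_range, 0.0, v)
        v = np.where(v < 0, 0.0, v)
        return cls(v, max_range=max_range)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    def validity(self, depth_range: tuple[float, float] | None = None) -> np.ndarray:
        """Boolean mask of pixels carrying a usable measurement.

        True iff depth > 0 and, when ``depth_range=(lo, hi)`` is given,
        ``lo <= depth <= hi``.
        """
        mask = self.values > 0
        if depth_range is not None:
            lo, hi = depth_range
            if lo < 0 or hi <= 0:
                raise ValueError(f"invalid depth range {depth_range}")
            mask &= (self.values >= lo) & (self.values <= hi)
        return mask


def encode_depth_png(d: DepthMap, path: str | Path) -> None:
    """Write a depth map as a 16-bit single-channel millimetre PNG.

    Stored value = ``round(depth_m * 1000)`` clipped to ``[0, 65535]``;
    0 stays 0 (missing).
    """
    mm = np.round(d.values * 1000.0)
    mm = np.clip(mm, 0, 65535).astype(np.uint16)
    Image.fromarray(mm).save(Path(path), format="PNG")


def decode_depth_png(path: str | Path, max_range: float = DEFAULT_MAX_RANGE) -> DepthMap:
    """Read a 16-bit millimetre PNG back into metres.

    Values decoding above ``max_range`` are treated as missing (set to 0):
    the encoder never writes them for data within range, so they indicate an
    out-of-range reading.

    Raises
    ------
    DepthFormatError
        If the file is not a single-channel 16-bit (or wider integer) PNG.
    """
    with Image.open(Path(path)) as im:
        if im.mode not in _DEPTH_MODES:
            raise DepthFormatError(
                f"{path}: expected single-channel 16-bit PNG, got mode {im.mode!r}"
                + (" (8-bit)" if im.mode == "L" else "")
                + (f" with {len(im.getbands())} channels" if len(im.getbands()) != 1 else "")
            )
        mm = np.asarray(im, dtype=np.int64)
    metres = mm.astype(float) / 1000.0
    return DepthMap.sanitize(metres, max_range=max_range)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read an instance-label image (0 = background) as an integer array."""
    with Image.open(Path(path)) as im:
        if im.mode not in ("L", "P") + _DEPTH_MODES:
            raise DepthFormatError(
                f"{path}: expected single-channel 8/16-bit label PNG, got mode {im.mode!r}"
            )
        labels = np.asarray(im.convert("I") if im.mode == "P" else im, dtype=np.int64)
    if np.any(labels < 0):
        raise DepthFormatError(f"{path}: negative label values")
    return labels


def write_mask_png(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    if np.any(labels < 0) or np.any(labels > 65535):
        raise ValueError("labels must fit an unsigned 16-bit PNG")
    if labels.max(initial=0) <= 255:
        Image.fromarray(labels.astype(np.uint8)).save(Path(path), format="PNG")
    else:
        Image.fromarray(labels.astype(np.uint16)).save(Path(path), format="PNG")


@dataclass
class ScenePair:
    """Files sharing one stem: RGB image, depth label, instance mask."""

    stem: str
    image: Path | None = None
    depth: Path | None = None
    mask: Path | None = None
    extra: dict[str, Path] = field(default_factory=dict)


def find_pairs(directory: str | Path) -> list[ScenePair]:
    """Group the PNGs of a fixture directory by shared stem.

    ``<stem>.png`` is the RGB image, ``<stem>_depth.png`` the depth label,
    ``<stem>_mask.png`` the instance mask; any other ``<stem>_<tag>.png``
    lands in ``extra`` (e.g. ``_pred`` for a predicted depth map).
    """
    directory = Path(directory)
    pairs: dict[str, ScenePair] = {}

    def entry(stem: str) -> ScenePair:
        return pairs.setdefault(stem, ScenePair(stem=stem))

    for p in sorted(directory.glob("*.png")):
        name = p.stem
        if name.endswith("_depth"):
            entry(name[: -len("_depth")]).depth = p
        elif name.endswith("_mask"):
            entry(name[: -len("_mask")]).mask = p
        elif "_" in name and name.rsplit("_", 1)[1].isalpha():
            stem, tag = name.rsplit("_", 1)
            entry(stem).extra[tag] = p
        else:
            entry(name).image = p
    return [pairs[s] for s in sorted(pairs)]
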