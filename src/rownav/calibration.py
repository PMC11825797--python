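"""Camera-migration calibration: input-resize and output-scale corrections.

A monocular depth network learns the pixel-represented focal length of its
training camera.  Deployed on a camera with a different focal length it
mis-scales depth roughly multiplicatively, which can push the absolute
relative error from a few percent to near 100%.  Two cheap corrections both
invert that multiplicative law:

* **input resize** — enlarge (or shrink) the input image by a factor ``s``
  before inference so its pixel focal length matches the training camera's,
  then map the prediction back to native resolution;
* **output scale** — divide the predicted depths by a constant ``k``.

Either factor is found by an explicit grid sweep that minimises a masked
depth metric (ABS-REL on the 0-5 m range by default) over a small paired
calibration set.  A grid is trivially reproducible and its score curve makes
mis-set bounds obvious, which is why no continuous optimiser is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import metrics as _metrics
from .depth_io import DepthMap

__all__ = [
    "DepthProvider",
    "CalibrationResult",
    "OBJECTIVES",
    "calibrate_output_scale",
    "calibrate_input_resize",
    "apply_correction",
]

#: Provider contract: ``provider(image, scale=1.0) -> DepthMap`` at the
#: scale-resized resolution; deterministic for fixed (image, scale).
DepthProvider = Callable[..., DepthMap]

OBJECTIVES: dict[str, Callable[[_metrics.DepthPair], float]] = {
    "abs_rel": _metrics.abs_rel,
    "rmse": _metrics.rmse,
    "rmse_log": _metrics.rmse_log,
    "sq_rel": _metrics.sq_rel,
    "silog": _metrics.silog_eval,
}

DEFAULT_SCALE_GRID = np.round(np.arange(0.25, 4.0 + 1e-9, 0.01), 10)
DEFAULT_RESIZE_GRID = np.round(np.arange(0.5, 4.0 + 1e-9, 0.02), 10)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a grid sweep.

    ``factor`` is the arg-min of ``scores`` over ``grid`` (ties break toward
    the smaller factor); ``objective_value`` is the score at the optimum.
    """

    method: str  # "input_resize" | "output_scale"
    factor: float
    objective: str
    objective_value: float
    grid: np.ndarray
    scores: np.ndarray

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "factor": self.factor,
            "objective": self.objective,
            "objective_value": self.objective_value,
            "grid": [float(g) for g in self.grid],
            "scores": [float(s) for s in self.scores],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _objective_fn(name: str) -> Callable[[_metrics.DepthPair], float]:
    try:
        return OBJECTIVES[name]
    except KeyError:
        raise ValueError(f"unknown objective {name!r}; choose from {sorted(OBJECTIVES)}")


def _mean_score(
    preds: Sequence[DepthMap],
    labels: Sequence[DepthMap],
    fn: Callable[[_metrics.DepthPair], float],
    depth_range: tuple[float, float],
) -> float:
    scores = []
    for pred, label in zip(preds, labels):
        pair = _metrics.DepthPair.from_maps(pred, label, depth_range=depth_range)
        scores.append(fn(pair))
    return float(np.mean(scores))


def _check_pairs(pairs) -> None:
    if not pairs:
        raise ValueError("calibration needs at least one (image, label) pair")


def calibrate_output_scale(
    provider: DepthProvider,
    pairs: Sequence[tuple[object, DepthMap]],
    grid: np.ndarray | None = None,
    objective: str = "abs_rel",
    depth_range: tuple[float, float] = (0.0, 5.0),
) -> CalibrationResult:
    """Find the constant ``k`` minimising the objective of ``pred / k``.

    The provider runs once per pair at native scale; only the predicted
    *values* are rescaled, never the images or labels.  Null predictions
    (0) stay null under every candidate ``k``.
    """
    _check_pairs(pairs)
    grid = DEFAULT_SCALE_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid must be non-empty with positive factors")
    fn = _objective_fn(objective)
    labels = [lab for _, lab in pairs]
    preds = [provider(img, 1.0) for img, _ in pairs]
    scores = np.empty(grid.size)
    for i, k in enumerate(grid):
        # score the raw rescaled values (no range cap) so the score curve is
        # continuous in k even where division pushes depths past the storage range
        scaled = [DepthMap(np.where(p.values > 0, p.values / k, 0.0),
                           max_range=np.inf) for p in preds]
        scores[i] = _mean_score(scaled, labels, fn, depth_range)
    best = int(np.argmin(scores))
    return CalibrationResult(
        method="output_scale",
        factor=float(grid[best]),
        objective=objective,
        objective_value=float(scores[best]),
        grid=grid,
        scores=scores,
    )


def _downscale_nearest(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    # order-0 resampling preserves values exactly, so the 0-null sentinel
    # never bleeds into valid depths
    return _sk_resize(values, shape, order=0, preserve_range=True,
                      anti_aliasing=False, mode="edge")


def calibrate_input_resize(
    provider: DepthProvider,
    pairs: Sequence[tuple[object, DepthMap]],
    grid: np.ndarray | None = None,
    objective: str = "abs_rel",
    depth_range: tuple[float, float] = (0.0, 5.0),
) -> CalibrationResult:
    """Find the input-resize factor ``s`` minimising the objective.

    For each ``s`` the provider runs on the ``s``-resized input; its
    prediction is mapped back to label resolution by nearest-neighbour
    (value-preserving) resampling before scoring.  Labels always stay at
    native resolution.
    """
    _check_pairs(pairs)
    grid = DEFAULT_RESIZE_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid must be non-empty with positive factors")
    fn = _objective_fn(objective)
    labels = [lab for _, lab in pairs]
    scores = np.empty(grid.size)
    for i, s in enumerate(grid):
        preds = []
        for (img, lab) in pairs:
            raw = provider(img, float(s))
            down = _downscale_nearest(raw.values, lab.values.shape)
            preds.append(DepthMap.sanitize(down, max_range=raw.max_range))
        scores[i] = _mean_score(preds, labels, fn, depth_range)
    best = int(np.argmin(scores))
    return CalibrationResult(
        method="input_resize",
        factor=float(grid[best]),
        objective=objective,
        objective_value=float(scores[best]),
        grid=grid,
        scores=scores,
    )


def apply_correction(depth: DepthMap, result: CalibrationResult) -> DepthMap:
    """Apply an output-scale correction to a depth map.

    Only ``output_scale`` results can be applied after the fact: an
    ``input_resize`` correction changes what the network sees and must be
    applied at inference time (resize the input, run the provider, map the
    prediction back).
    """
    if result.method != "output_scale":
        raise ValueError(
            f"cannot apply a {result.method!r} correction to an existing depth map; "
            "input resizing must happen at inference time"
        )
    v = np.where(depth.values > 0, depth.values / result.factor, 0.0)
    return DepthMap.sanitize(v, max_range=depth.max_range)
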