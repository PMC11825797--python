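"""Masked depth-evaluation metrics, the scale-invariant log loss, and chamfer distance.

All depth metrics are evaluated only where the ground-truth map carries a
valid (non-null, in-range) measurement; the validity mask is shared by every
metric so the eight scores of a report always describe the same pixel set.
Writing ``d_i = log y^pred_i - log y^gt_i`` over the N masked pixels:

========  =====================================================
ABS-REL   ``100/N * sum |y_pred - y_gt| / y_gt``  (percent)
RMSE      ``sqrt(1/N * sum (y_pred - y_gt)^2)``  (metres)
Silog     ``1/N sum d_i^2 - (1/N sum d_i)^2``  (variance form)
delta_n   ``100/N * #{ max(y_gt/y_pred, y_pred/y_gt) < 1.25^n }``
RMSElog   ``sqrt(1/N * sum d_i^2)``
SQ-REL    ``1/N * sum ((y_pred - y_gt) / y_gt)^2``
========  =====================================================

The variance form of Silog is the scale-invariant log error of the Eigen
lineage: it is exactly zero whenever the prediction is a constant multiple of
the truth, which is what makes it useful for diagnosing global scale bias.
A literal sum form (``+`` instead of ``-`` between the two terms) is
selectable but is *not* scale-invariant; see :func:`silog_eval`.

Chamfer distance between point clouds uses the squared bidirectional
convention: mean squared nearest-neighbour distance from A to B plus the same
from B to A.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .depth_io import DepthMap

__all__ = [
    "DepthPair",
    "MetricReport",
    "abs_rel",
    "rmse",
    "rmse_log",
    "sq_rel",
    "delta_accuracy",
    "silog_eval",
    "silog_loss",
    "chamfer_distance",
    "evaluate",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class DepthPair:
    """A prediction/label pair with the shared validity mask.

    ``mask`` is True exactly where the label is valid (non-null and within the
    evaluation range); metrics read only those pixels.
    """

    pred: np.ndarray
    label: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.pred.shape == self.label.shape == self.mask.shape):
            raise ValueError(
                f"shape mismatch: pred {self.pred.shape}, label {self.label.shape}, "
                f"mask {self.mask.shape}"
            )

    @classmethod
    def from_maps(
        cls,
        pred: DepthMap,
        label: DepthMap,
        depth_range: tuple[float, float] | None = None,
    ) -> "DepthPair":
        """Pair two depth maps, masking on the label's validity.

        ``depth_range=(lo, hi)`` restricts evaluation to label depths within
        that interval, e.g. ``(0, 5)`` for near-field navigation use.
        """
        mask = label.validity(depth_range)
        return cls(pred=np.asarray(pred.values, float),
                   label=np.asarray(label.values, float), mask=mask)

    @property
    def n(self) -> int:
        """Number of valid label pixels."""
        return int(np.count_nonzero(self.mask))

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        """(pred, label) restricted to the valid pixels; errors if none."""
        if self.n == 0:
            raise ValueError("no valid pixels under the mask; cannot evaluate metrics")
        return self.pred[self.mask], self.label[self.mask]


def _masked_positive(pair: DepthPair) -> tuple[np.ndarray, np.ndarray]:
    """Masked values for log-based metrics; rejects non-positive predictions."""
    p, g = pair.masked()
    bad = int(np.count_nonzero(p <= 0))
    if bad:
        raise ValueError(
            f"{bad} masked pixel(s) have non-positive predicted depth; "
            "log-based metrics are undefined there"
        )
    if np.any(g <= 0):  # cannot happen for a mask derived from validity()
        raise ValueError("masked ground truth contains non-positive depths")
    return p, g


def abs_rel(pair: DepthPair) -> float:
    """Mean absolute relative error, percent."""
    p, g = pair.masked()
    return float(100.0 * np.mean(np.abs(p - g) / g))


def rmse(pair: DepthPair) -> float:
    """Root mean squared error, metres."""
    p, g = pair.masked()
    return float(np.sqrt(np.mean((p - g) ** 2)))


def rmse_log(pair: DepthPair) -> float:
    """Root mean squared error of natural-log depths."""
    p, g = _masked_positive(pair)
    return float(np.sqrt(np.mean((np.log(p) - np.log(g)) ** 2)))


def sq_rel(pair: DepthPair) -> float:
    """Mean squared relative error."""
    p, g = pair.masked()
    return float(np.mean(((p - g) / g) ** 2))


def delta_accuracy(pair: DepthPair, n: int = 1) -> float:
    """Threshold accuracy delta_n: percent of pixels with ratio below 1.25**n.

    A pixel counts iff ``max(gt/pred, pred/gt) < 1.25**n`` (strict).
    """
    if n not in (1, 2, 3):
        raise ValueError(f"n must be 1, 2 or 3, got {n}")
    p, g = _masked_positive(pair)
    ratio = np.maximum(g / p, p / g)
    return float(100.0 * np.mean(ratio < 1.25 ** n))


def silog_eval(pair: DepthPair, form: str = "variance") -> float:
    """Scale-invariant log error.

    Parameters
    ----------
    form :
        ``"variance"`` (default): ``mean(d^2) - mean(d)^2``, zero under any
        constant multiplicative bias.  ``"sum"``: the literal
        ``mean(d^2) + mean(d)^2`` variant, which penalises global bias and is
        not scale-invariant.
    """
    p, g = _masked_positive(pair)
    d = np.log(p) - np.log(g)
    m1 = float(np.mean(d))
    m2 = float(np.mean(d ** 2))
    if form == "variance":
        var = float(np.mean((d - m1) ** 2))  # two-pass form: stable under cancellation
        # below the floating-point resolution of m2 the variance is
        # indistinguishable from zero (pred is a constant multiple of gt)
        if var <= 16 * np.finfo(float).eps * m2:
            return 0.0
        return var
    if form == "sum":
        return m2 + m1 ** 2
    raise ValueError(f"unknown silog form {form!r}")


def silog_loss(pair: DepthPair, lam: float = 0.85, alpha: float = 10.0) -> float:
    """Training-style silog loss ``alpha * sqrt(mean(d^2) - lam * mean(d)^2)``.

    Matches the masked loss used to train depth networks on sparse labels:
    null label pixels never contribute.  ``lam`` in (0, 1] trades off absolute
    versus scale-invariant error; ``lam=1`` reduces to ``alpha * std(d)``.
    """
    p, g = _masked_positive(pair)
    d = np.log(p) - np.log(g)
    radicand = float(np.mean(d ** 2)) - lam * float(np.mean(d)) ** 2
    if radicand < 0:
        warnings.warn("silog radicand below zero (constant-offset d with lam >= 1); clamped to 0")
        radicand = 0.0
    return alpha * float(np.sqrt(radicand))


def chamfer_distance(cloud_a: np.ndarray, cloud_b: np.ndarray, squared: bool = True) -> float:
    """Symmetric chamfer distance between two point sets.

    ``mean_a min_b d(a,b)^2 + mean_b min_a d(a,b)^2`` by default; with
    ``squared=False`` the unsquared distances are averaged instead.

    Raises
    ------
    ValueError
        If either cloud is empty — usually a sign that upstream depth
        filtering removed every point.
    """
    a = np.atleast_2d(np.asarray(cloud_a, dtype=float))
    b = np.atleast_2d(np.asarray(cloud_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("chamfer distance requires two non-empty point clouds")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    if squared:
        return float(np.mean(d_ab ** 2) + np.mean(d_ba ** 2))
    return float(np.mean(d_ab) + np.mean(d_ba))


@dataclass(frozen=True)
class MetricReport:
    """The eight depth scores; percentages for ABS-REL and the deltas."""

    abs_rel: float
    rmse: float
    silog: float
    delta1: float
    delta2: float
    delta3: float
    rmse_log: float
    sq_rel: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def format_row(self) -> str:
        """One table-style line: ABS-REL RMSE Silog d1 d2 d3 RMSElog SQ-REL."""
        return (
            f"ABS-REL {self.abs_rel:6.1f}%  RMSE {self.rmse:6.3f}  Silog {self.silog:6.3f}  "
            f"d1 {self.delta1:5.1f}%  d2 {self.delta2:5.1f}%  d3 {self.delta3:5.1f}%  "
            f"RMSElog {self.rmse_log:6.3f}  SQ-REL {self.sq_rel:6.3f}"
        )


def evaluate(pair: DepthPair, silog_form: str = "variance") -> MetricReport:
    """All eight metrics on the identical mask."""
    return MetricReport(
        abs_rel=abs_rel(pair),
        rmse=rmse(pair),
        silog=silog_eval(pair, form=silog_form),
        delta1=delta_accuracy(pair, 1),
        delta2=delta_accuracy(pair, 2),
        delta3=delta_accuracy(pair, 3),
        rmse_log=rmse_log(pair),
        sq_rel=sq_rel(pair),
    )


def evaluate_dataset(pairs: list[DepthPair], silog_form: str = "variance") -> MetricReport:
    """Unweighted mean of per-image metric reports."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    reports = [evaluate(p, silog_form=silog_form) for p in pairs]
    return MetricReport(
        **{
            f.name: float(np.mean([getattr(r, f.name) for r in reports]))
            for f in fields(MetricReport)
        }
    )
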