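"""Evaluation metrics: pixel accuracy, Dice overlap, average surface
distance, pubic-symphysis endpoint errors, and angle-difference summaries.

All pixel-space metrics are computed at the processing resolution of the
masks they are given; distances are Euclidean between pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import AoPKeyPoints, Point2D

__all__ = [
    "ConfusionCounts",
    "SegmentationReport",
    "AoPErrorSummary",
    "confusion",
    "pixel_accuracy",
    "multiclass_accuracy",
    "dice_score",
    "average_surface_distance",
    "endpoint_errors",
    "aop_error_summary",
    "segmentation_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class SegmentationReport:
    acc: float
    dice_all: float
    dice_ps: float
    dice_fh: float
    asd: float


@dataclass(frozen=True)
class AoPErrorSummary:
    mean_deg: float
    median_deg: float
    std_deg: float
    n: int
    n_over_20: int


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def confusion(pred: np.ndarray, truth: np.ndarray, class_id: int) -> ConfusionCounts:
    """One-vs-rest pixel confusion counts for a single class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_shapes(pred, truth)
    p = pred == class_id
    t = truth == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    return (c.TP + c.TN) / c.total


def multiclass_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Overall per-pixel agreement over all classes."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_shapes(pred, truth)
    return float(np.count_nonzero(pred == truth) / pred.size)


def dice_score(pred: np.ndarray, truth: np.ndarray, classes: int | list[int],
               aggregation: str = "pooled") -> float:
    """Dice overlap ``2 TP / (2 TP + FP + FN)``.

    For a list of classes, ``pooled`` (default) accumulates TP/FP/FN over
    the classes jointly (micro average); ``mean`` averages the per-class
    Dice values instead.  An empty union (class absent from both masks) is
    defined as perfect agreement (Dice = 1).
    """
    if isinstance(classes, int):
        classes = [classes]
    if aggregation not in ("pooled", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if aggregation == "mean" and len(classes) > 1:
        return float(np.mean([dice_score(pred, truth, c) for c in classes]))
    tp = fp = fn = 0
    for c in classes:
        cc = confusion(pred, truth, c)
        tp += cc.TP
        fp += cc.FP
        fn += cc.FN
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2 * tp / denom


def _surface_points(mask: np.ndarray, class_id: int) -> np.ndarray:
    """All boundary pixels of a class (every component; border counts outside)."""
    binary = np.asarray(mask) == class_id
    interior = (
        binary
        & np.roll(binary, 1, axis=0)
        & np.roll(binary, -1, axis=0)
        & np.roll(binary, 1, axis=1)
        & np.roll(binary, -1, axis=1)
    )
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    rows, cols = np.nonzero(binary & ~interior)
    return np.column_stack([cols, rows]).astype(float)


def average_surface_distance(a: np.ndarray, b: np.ndarray, class_id: int) -> float:
    """Symmetrized average surface distance in pixels.

    ``ASD(A, B) = (sum_{s in S(A)} d(s, S(B)) + sum_{s in S(B)} d(s, S(A)))
    / (|S(A)| + |S(B)|)`` where S(.) is the set of boundary pixels of the
    class (all connected components) and d is the Euclidean nearest-point
    distance between pixel centers.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    _check_shapes(a, b)
    sa = _surface_points(a, class_id)
    sb = _surface_points(b, class_id)
    if sa.size == 0 or sb.size == 0:
        raise ValueError(f"class {class_id} has an empty surface in one of the masks")
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


def endpoint_errors(
    pred: AoPKeyPoints | tuple[Point2D, Point2D],
    truth: tuple[Point2D, Point2D],
) -> tuple[float, float, float]:
    """(ED_U, ED_L, Ax): endpoint distances and long-axis angle error.

    ``pred`` provides the predicted upper/lower PS endpoints (Up, Lp);
    ``truth`` is the reference pair (U_t, L_t).  ED values are Euclidean
    distances in pixels; Ax is the angle in degrees between the predicted
    axis ``Lp - Up`` and the reference axis ``L_t - U_t``.
    """
    if isinstance(pred, AoPKeyPoints):
        up, lp = pred.Up, pred.Lp
    else:
        up, lp = pred
    ut, lt = truth
    ed_u = float(np.hypot(ut.x - up.x, ut.y - up.y))
    ed_l = float(np.hypot(lt.x - lp.x, lt.y - lp.y))
    xp = lp.as_array() - up.as_array()
    xt = lt.as_array() - ut.as_array()
    np_, nt = np.linalg.norm(xp), np.linalg.norm(xt)
    if np_ == 0 or nt == 0:
        raise ValueError("zero-length PS axis")
    c = float(np.clip(xp @ xt / (np_ * nt), -1.0, 1.0))
    return ed_u, ed_l, float(np.degrees(np.arccos(c)))


def aop_error_summary(
    pred_aops, truth_aops, std: str = "population"
) -> AoPErrorSummary:
    """Summaries of the absolute angle differences |AoP_p - AoP_t|.

    Standard deviation is the population form (divide by n) by default;
    pass ``std="sample"`` for the n-1 form.
    """
    pred = np.asarray(pred_aops, dtype=float)
    truth = np.asarray(truth_aops, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("need equal-length, non-empty angle lists")
    delta = np.abs(pred - truth)
    ddof = 0 if std == "population" else 1
    return AoPErrorSummary(
        mean_deg=float(delta.mean()),
        median_deg=float(np.median(delta)),
        std_deg=float(delta.std(ddof=ddof)),
        n=int(delta.size),
        n_over_20=int(np.count_nonzero(delta > 20.0)),
    )


def segmentation_report(pred: np.ndarray, truth: np.ndarray,
                        dice_all: str = "pooled") -> SegmentationReport:
    """Per-image segmentation metrics against a reference mask.

    ``acc`` is the overall multi-class per-pixel agreement; ``dice_all``
    pools the PS and FH classes (or averages them with ``dice_all="mean"``);
    ``asd`` averages the per-class average surface distances of PS and FH
    (classes absent from either mask are skipped; NaN if none is measurable).
    """
    from .geometry import FH_CLASS, PS_CLASS

    asds = []
    for c in (PS_CLASS, FH_CLASS):
        try:
            asds.append(average_surface_distance(pred, truth, c))
        except ValueError:
            pass
    return SegmentationReport(
        acc=multiclass_accuracy(pred, truth),
        dice_all=dice_score(pred, truth, [PS_CLASS, FH_CLASS], aggregation=dice_all),
        dice_ps=dice_score(pred, truth, PS_CLASS),
        dice_fh=dice_score(pred, truth, FH_CLASS),
        asd=float(np.mean(asds)) if asds else float("nan"),
    )
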