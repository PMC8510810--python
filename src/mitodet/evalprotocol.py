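"""ICPR-contest-style mitosis scoring.

A detection counts as a true positive when the center of its bounding
box (the intersection of its diagonals) lies within 8 micrometres of an
unclaimed ground-truth point; the scan resolution (microns per pixel)
converts that radius into pixels.  Matching is one-to-one and greedy by
descending confidence, each detection claiming its nearest unclaimed
ground-truth point in range.  From the resulting TP/FP/FN counts:

    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Recall * Precision / (Recall + Precision)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mitodet.labelgen import BoundingBox, WeakLabel

__all__ = [
    "ResolutionSpec", "ConfusionCounts", "DetectionMetrics",
    "box_center", "match_detections", "compute_metrics", "f1_from_pr",
]


@dataclass(frozen=True)
class ResolutionSpec:
    """Physical scan resolution and the center-distance match radius.

    ``microns_per_pixel`` is the scanner pixel pitch (e.g. 0.25 for an
    Aperio Scanscope XT at 40x); ``match_radius_um`` defaults to the
    contest criterion of 8 micrometres.
    """

    microns_per_pixel: float
    match_radius_um: float = 8.0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.match_radius_um <= 0:
            raise ValueError("match_radius_um must be > 0")

    @property
    def radius_px(self) -> float:
        return self.match_radius_um / self.microns_per_pixel


@dataclass(frozen=True)
class ConfusionCounts:
    """TP = detected true mitoses, FP = spurious detections, FN = misses."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True


def box_center(box: BoundingBox) -> tuple[float, float]:
    """Diagonal intersection of the box: ((x0+x1)/2, (y0+y1)/2)."""
    return box.center()


def match_detections(
    detections: list,
    gt_points: list[WeakLabel],
    res: ResolutionSpec,
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one center-distance matching.

    ``detections`` may hold Detection objects (``.box``, ``.confidence``),
    bare BoundingBoxes, or (x, y[, confidence]) center tuples.  In
    descending confidence order each detection claims the nearest
    unclaimed ground-truth point within ``res.radius_px``.  Returns the
    confusion counts and the (detection_index, gt_index) match pairs.
    Conservation holds by construction: tp + fn = len(gt_points) and
    tp + fp = len(detections).
    """
    centers = []
    confs = []
    for det in detections:
        if hasattr(det, "box"):
            centers.append(box_center(det.box))
            confs.append(getattr(det, "confidence", 1.0))
        elif isinstance(det, BoundingBox):
            centers.append(box_center(det))
            confs.append(1.0)
        else:
            centers.append((float(det[0]), float(det[1])))
            confs.append(float(det[2]) if len(det) > 2 else 1.0)

    radius = res.radius_px
    order = sorted(range(len(centers)), key=lambda i: (-confs[i], i))
    claimed: set[int] = set()
    matches: list[tuple[int, int]] = []
    for i in order:
        cx, cy = centers[i]
        best_j, best_d = -1, math.inf
        for j, gt in enumerate(gt_points):
            if j in claimed:
                continue
            d = math.hypot(cx - gt.x, cy - gt.y)
            if d <= radius and d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            claimed.add(best_j)
            matches.append((i, best_j))
    tp = len(matches)
    counts = ConfusionCounts(tp=tp, fp=len(centers) - tp, fn=len(gt_points) - tp)
    return counts, sorted(matches)


def compute_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    """Precision, recall and F1 from confusion counts.

    With no detections at all precision is undefined; it is reported as
    0 with ``precision_defined=False`` so batch evaluation never aborts.
    Likewise recall with no ground truth.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    p_def = (tp + fp) > 0
    r_def = (tp + fn) > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        f1=f1_from_pr(recall, precision),
        precision_defined=p_def,
        recall_defined=r_def,
    )


def f1_from_pr(recall: float, precision: float) -> float:
    """Harmonic mean 2*R*P/(R+P); defined as 0 when both are 0."""
    if not (0.0 <= recall <= 1.0 and 0.0 <= precision <= 1.0):
        raise ValueError("recall and precision must lie in [0, 1]")
    if recall + precision == 0.0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)
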