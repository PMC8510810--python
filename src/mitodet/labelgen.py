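"""Weak-to-strong label generation.

Converts a predicted mitosis probability map plus weak center-point
annotations into bounding-box "strong" labels: threshold the foreground
probability, extract 8-connected components, take each component's
minimum circumscribed (axis-aligned) rectangle, and mark a box positive
when a weak label point falls inside it.  Boxes containing no weak point
are kept as negative candidates (segmentation false positives); weak
points landing in no box are reported as unmatched rather than being
turned into fabricated boxes.

Coordinate conventions, fixed package-wide: 0-based pixels, x = column,
y = row, boxes half-open [x0, x1) x [y0, y1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from mitodet.segnet import ProbabilityMap

__all__ = [
    "BoundingBox", "WeakLabel", "LabeledBox", "binarize_probmap",
    "extract_components", "min_bounding_rect", "assign_weak_labels",
    "generate_strong_labels",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle, half-open: covers pixels [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box ({self.x0}, {self.y0}, {self.x1}, {self.y1})")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Boundary-inclusive on the closed pixel extent [x0, x1-1] x [y0, y1-1]."""
        return self.x0 <= x <= self.x1 - 1 and self.y0 <= y <= self.y1 - 1


@dataclass(frozen=True)
class WeakLabel:
    """A single center-point annotation of one mitosis (x = column, y = row)."""

    x: float
    y: float


@dataclass(frozen=True)
class LabeledBox:
    """A generated box, positive iff it matched a weak label."""

    box: BoundingBox
    positive: bool
    matched_weak_label: WeakLabel | None = None

    def __post_init__(self) -> None:
        if self.positive != (self.matched_weak_label is not None):
            raise ValueError("positive flag must match presence of a weak label")


def binarize_probmap(probmap: ProbabilityMap | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask where the mitosis-class probability is >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if isinstance(probmap, ProbabilityMap):
        fg = probmap.mitosis_prob()
    else:
        fg = np.asarray(probmap)
        if fg.ndim == 3:
            fg = fg[..., 1]
    return fg >= threshold


def extract_components(mask: np.ndarray, min_area: int = 5) -> list[np.ndarray]:
    """8-connected components of a binary mask as (n_i, 2) arrays of (x, y).

    Components smaller than ``min_area`` pixels are dropped — they are
    almost always threshold speckle rather than a nucleus.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    components = []
    for idx in range(1, n + 1):
        ys, xs = np.nonzero(labeled == idx)
        if xs.size >= min_area:
            components.append(np.column_stack([xs, ys]))
    return components


def min_bounding_rect(component: np.ndarray) -> BoundingBox:
    """Minimum circumscribed axis-aligned rectangle of a pixel set.

    For pixels with min/max column x and row y the half-open box is
    [min x, max x + 1) x [min y, max y + 1).
    """
    pts = np.asarray(component)
    if pts.size == 0:
        raise ValueError("empty component has no bounding rectangle")
    xs, ys = pts[:, 0], pts[:, 1]
    return BoundingBox(
        x0=int(xs.min()), y0=int(ys.min()),
        x1=int(xs.max()) + 1, y1=int(ys.max()) + 1,
    )


def assign_weak_labels(
    boxes: list[BoundingBox], points: list[WeakLabel],
) -> tuple[list[LabeledBox], list[WeakLabel]]:
    """Mark each box positive iff a weak label lies inside it.

    Point-in-box is boundary-inclusive on the closed pixel extent.  Each
    point matches at most one box: when a point sits inside several
    (nested or overlapping) boxes it goes to the box whose center is
    nearest, ties broken by smaller area then insertion order.  Returns
    the labeled boxes plus the points that fell inside no box (mitoses
    the segmentation missed).
    """
    matched: dict[int, WeakLabel] = {}
    claimed: set[int] = set()
    unmatched: list[WeakLabel] = []
    for pt in points:
        candidates = [
            i for i, b in enumerate(boxes)
            if i not in claimed and b.contains_point(pt.x, pt.y)
        ]
        if not candidates:
            unmatched.append(pt)
            continue

        def rank(i: int) -> tuple[float, float, int]:
            cx, cy = boxes[i].center()
            return ((cx - pt.x) ** 2 + (cy - pt.y) ** 2, boxes[i].area, i)

        best = min(candidates, key=rank)
        matched[best] = pt
        claimed.add(best)
    labeled = [
        LabeledBox(box=b, positive=i in matched, matched_weak_label=matched.get(i))
        for i, b in enumerate(boxes)
    ]
    return labeled, unmatched


def generate_strong_labels(
    probmap: ProbabilityMap | np.ndarray,
    points: list[WeakLabel],
    threshold: float = 0.5,
    min_area: int = 5,
) -> tuple[list[LabeledBox], list[WeakLabel]]:
    """Full phase-1 output for one tile: probability map -> labeled boxes.

    Chains :func:`binarize_probmap`, :func:`extract_components`,
    :func:`min_bounding_rect` and :func:`assign_weak_labels`.
    """
    mask = binarize_probmap(probmap, threshold)
    components = extract_components(mask, min_area=min_area)
    boxes = [min_bounding_rect(comp) for comp in components]
    return assign_weak_labels(boxes, points)
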