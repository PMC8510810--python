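"""Readers/writers for the pipeline's file formats.

CSV dialects (all headerless, 0-based pixel coordinates, x = column):

* weak labels — ``x,y[,...]`` one mitosis center per row; extra columns
  (e.g. annotator confidence) are ignored.
* boxes — ``x0,y0,x1,y1[,positive|confidence]``: a trailing integer
  0/1 marks a generated label's positivity, a trailing float a
  detection confidence.
* centers — ``x,y,confidence`` (box centers, the contest submission
  form).

Images and masks travel as PNG; masks are 0/255.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from mitodet.detector import Detection
from mitodet.evalprotocol import box_center
from mitodet.labelgen import BoundingBox, LabeledBox, WeakLabel

__all__ = [
    "ImageTile", "ParseError", "read_weak_labels", "write_weak_labels",
    "read_boxes", "write_boxes", "write_boxes_json", "write_centers",
    "read_image", "write_image", "read_mask", "write_mask",
    "write_metrics", "write_match_report", "stage_seed",
]


@dataclass
class ImageTile:
    """An RGB tile with its physical resolution in microns per pixel."""

    image: np.ndarray
    microns_per_pixel: float = 0.25

    @property
    def shape(self) -> tuple[int, ...]:
        return self.image.shape


class ParseError(ValueError):
    """A malformed row in one of the CSV dialects."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_weak_labels(path: str | Path) -> list[WeakLabel]:
    """Parse an ICPR-style weak-label CSV: ``x,y`` per row, no header."""
    points = []
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(path, line_no, f"expected >= 2 columns, got {len(row)}")
            try:
                x, y = float(row[0]), float(row[1])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric coordinate: {exc}") from None
            points.append(WeakLabel(x=x, y=y))
    return points


def write_weak_labels(path: str | Path, points: list[WeakLabel]) -> None:
    with open(path, "w", newline="") as fh:
        for p in points:
            fh.write(f"{_fmt(p.x)},{_fmt(p.y)}\n")


def write_boxes(path: str | Path, boxes: list) -> None:
    """Write boxes; LabeledBox gains a 0/1 column, Detection a float one."""
    with open(path, "w", newline="") as fh:
        for item in boxes:
            if isinstance(item, LabeledBox):
                b = item.box
                extra = f",{int(item.positive)}"
            elif isinstance(item, Detection):
                b = item.box
                extra = f",{repr(float(item.confidence))}"
            else:
                b, extra = item, ""
            fh.write(f"{_fmt(b.x0)},{_fmt(b.y0)},{_fmt(b.x1)},{_fmt(b.y1)}{extra}\n")


def read_boxes(path: str | Path) -> list:
    """Inverse of :func:`write_boxes`; element type follows the 5th column.

    Four columns yield BoundingBox, a trailing bare 0/1 a LabeledBox,
    and a trailing float (decimal point present) a Detection.  Boxes
    violating x1 > x0, y1 > y0 raise a :class:`ParseError`.
    """
    out = []
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4:
                raise ParseError(path, line_no, f"expected >= 4 columns, got {len(row)}")
            try:
                coords = [float(c) for c in row[:4]]
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric coordinate: {exc}") from None
            try:
                box = BoundingBox(*coords)
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from None
            if len(row) == 4:
                out.append(box)
                continue
            extra = row[4].strip()
            if extra in ("0", "1"):
                positive = extra == "1"
                out.append(LabeledBox(
                    box=box, positive=positive,
                    matched_weak_label=WeakLabel(*box.center()) if positive else None,
                ))
            else:
                try:
                    conf = float(extra)
                except ValueError as exc:
                    raise ParseError(path, line_no, f"bad 5th column: {exc}") from None
                out.append(Detection(box=box, confidence=conf))
    return out


def write_boxes_json(path: str | Path, boxes: list) -> None:
    """JSON twin of :func:`write_boxes` for generated labels."""
    records = []
    for item in boxes:
        if isinstance(item, LabeledBox):
            rec = {"x0": item.box.x0, "y0": item.box.y0,
                   "x1": item.box.x1, "y1": item.box.y1,
                   "positive": item.positive}
            if item.matched_weak_label is not None:
                rec["weak_label"] = {"x": item.matched_weak_label.x,
                                     "y": item.matched_weak_label.y}
        elif isinstance(item, Detection):
            rec = {"x0": item.box.x0, "y0": item.box.y0,
                   "x1": item.box.x1, "y1": item.box.y1,
                   "confidence": item.confidence}
        else:
            rec = {"x0": item.x0, "y0": item.y0, "x1": item.x1, "y1": item.y1}
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=2))


def write_centers(path: str | Path, detections: list[Detection]) -> None:
    """ICPR-style submission: ``x,y,confidence`` from box centers."""
    with open(path, "w", newline="") as fh:
        for d in detections:
            cx, cy = box_center(d.box)
            fh.write(f"{_fmt(cx)},{_fmt(cy)},{repr(float(d.confidence))}\n")


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool).astype(np.uint8) * 255))


def write_metrics(path: str | Path, counts, metrics) -> dict:
    payload = {
        "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
        "precision": metrics.precision, "recall": metrics.recall, "f1": metrics.f1,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def write_match_report(path: str | Path, detections: list, gt_points,
                       matches: list[tuple[int, int]]) -> None:
    """Per-detection match CSV: ``det_x,det_y,confidence,status,gt_x,gt_y``."""
    matched = dict(matches)
    with open(path, "w", newline="") as fh:
        fh.write("det_x,det_y,confidence,status,gt_x,gt_y\n")
        for i, det in enumerate(detections):
            if hasattr(det, "box"):
                cx, cy = box_center(det.box)
                conf = getattr(det, "confidence", 1.0)
            else:
                cx, cy = float(det[0]), float(det[1])
                conf = float(det[2]) if len(det) > 2 else 1.0
            if i in matched:
                g = gt_points[matched[i]]
                fh.write(f"{_fmt(cx)},{_fmt(cy)},{conf!r},TP,{_fmt(g.x)},{_fmt(g.y)}\n")
            else:
                fh.write(f"{_fmt(cx)},{_fmt(cy)},{conf!r},FP,,\n")
        claimed = set(matched.values())
        for j, g in enumerate(gt_points):
            if j not in claimed:
                fh.write(f",,,FN,{_fmt(g.x)},{_fmt(g.y)}\n")


_STAGE_OFFSETS = {
    "synth": 101,
    "segnet": 211,
    "seg_train": 307,
    "detector": 401,
    "eval": 503,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan one pipeline seed out to a fixed per-stage seed (< 2**31)."""
    return (int(global_seed) + _STAGE_OFFSETS[stage]) % (2 ** 31)
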