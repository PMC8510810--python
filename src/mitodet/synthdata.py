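"""Seeded generator of H&E-like tiles with exact ground truth.

Each tile is a pink, lightly textured eosin-style background carrying
two blob populations: dark hyperchromatic "mitotic" figures (irregular
perturbed ellipses, recorded in the mask) and lighter distractor nuclei
that look similar but are absent from the mask — emulating the normal
nuclei that make mitotic counting error-prone.  Every tile comes with a
pixel mask, per-blob minimum bounding boxes and centroid weak labels in
the exact dialects the rest of the pipeline consumes.

Realism is deliberately limited to geometry, color contrast and label
structure; there is no stain physics, chromatin texture or overlap of
figures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from mitodet.labelgen import BoundingBox, WeakLabel, extract_components, min_bounding_rect

__all__ = ["SynthConfig", "SynthTile", "PlacementError", "generate_tile", "generate_dataset"]


class PlacementError(RuntimeError):
    """Raised when the requested blob count cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} mitoses under the "
            "configured separation constraint"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``mitosis_axes_range`` bounds the ellipse semi-axes in pixels;
    ``irregularity`` scales a low-order harmonic perturbation of the
    blob boundary (0 = perfect ellipse).  Colors are mean RGB values of
    a Gaussian noise model.  ``min_separation_px`` is the minimum gap
    between blob boundaries, which guarantees each mitosis is its own
    8-connected mask component.
    """

    tile_size: tuple[int, int] = (64, 64)
    n_mitoses: int = 3
    n_mitoses_range: tuple[int, int] | None = None
    n_distractors: int = 6
    mitosis_axes_range: tuple[float, float] = (2.5, 5.0)
    irregularity: float = 0.25
    background_rgb: tuple[float, float, float] = (228.0, 192.0, 214.0)
    mitosis_rgb: tuple[float, float, float] = (72.0, 40.0, 98.0)
    distractor_rgb: tuple[float, float, float] = (158.0, 118.0, 176.0)
    noise_sd: float = 7.0
    min_separation_px: float = 3.0
    centroid_jitter_sd: float = 0.0
    microns_per_pixel: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.tile_size
        if min(h, w) < 32:
            raise ValueError("tile_size must be at least 32x32")
        lo, hi = self.mitosis_axes_range
        if not (0 < lo <= hi):
            raise ValueError("mitosis_axes_range must be positive and ordered")
        if 2 * hi >= min(h, w):
            raise ValueError("mitosis axes do not fit inside the tile")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be >= 0")


@dataclass
class SynthTile:
    """One generated tile with its complete ground truth."""

    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) bool, mitoses only
    boxes: list[BoundingBox]
    weak_labels: list[WeakLabel]
    microns_per_pixel: float = 0.25


def _blob_mask(shape: tuple[int, int], cx: float, cy: float, ax: float, ay: float,
               phi: float, irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterise one perturbed ellipse; returns a boolean (H, W) mask."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    rho = np.sqrt((u / ax) ** 2 + (v / ay) ** 2)
    theta = np.arctan2(dy, dx)
    bump = np.zeros(shape)
    for k in (2, 3, 4):
        bump += (rng.normal(0.0, 1.0) * np.cos(k * theta)
                 + rng.normal(0.0, 1.0) * np.sin(k * theta)) / k
    boundary = 1.0 + irregularity * bump / 3.0
    return rho <= np.clip(boundary, 0.4, 1.6)


def generate_tile(cfg: SynthConfig) -> SynthTile:
    """Generate one tile; fully determined by ``cfg`` (including its seed).

    Mitoses are placed first, then distractors, each by rejection
    sampling against the separation constraint.  Failing to place the
    requested mitosis count raises :class:`PlacementError`; distractors
    are best-effort decoration and are silently dropped on failure.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.tile_size
    lo, hi = cfg.mitosis_axes_range
    if cfg.n_mitoses_range is not None:
        n_mitoses = int(rng.integers(cfg.n_mitoses_range[0], cfg.n_mitoses_range[1] + 1))
    else:
        n_mitoses = cfg.n_mitoses

    # background: mean color + smooth texture + pixel noise
    image = np.empty((h, w, 3))
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=5.0)
    texture = texture / max(np.abs(texture).max(), 1e-9) * 12.0
    for ch in range(3):
        image[..., ch] = cfg.background_rgb[ch] + texture
    image += rng.normal(0.0, cfg.noise_sd, size=image.shape)

    placed: list[tuple[float, float, float]] = []  # (cx, cy, effective radius)

    def try_place(count: int, strict: bool) -> list[tuple[float, float, float, float, float]]:
        specs = []
        for _ in range(count):
            ok = False
            for _attempt in range(200):
                ax = rng.uniform(lo, hi)
                ay = rng.uniform(lo, hi)
                phi = rng.uniform(0.0, np.pi)
                r = max(ax, ay) * 1.6  # boundary perturbation can reach 1.6x
                cx = rng.uniform(r + 1, w - r - 2)
                cy = rng.uniform(r + 1, h - r - 2)
                if all(
                    np.hypot(cx - px, cy - py) >= r + pr + cfg.min_separation_px
                    for px, py, pr in placed
                ):
                    placed.append((cx, cy, r))
                    specs.append((cx, cy, ax, ay, phi))
                    ok = True
                    break
            if not ok and strict:
                raise PlacementError(count, len(specs))
        return specs

    mitosis_specs = try_place(n_mitoses, strict=True)
    distractor_specs = try_place(cfg.n_distractors, strict=False)

    mask = np.zeros((h, w), dtype=bool)
    for cx, cy, ax, ay, phi in mitosis_specs:
        blob = _blob_mask((h, w), cx, cy, ax, ay, phi, cfg.irregularity, rng)
        mask |= blob
        color = np.array(cfg.mitosis_rgb) + rng.normal(0.0, 6.0, size=3)
        image[blob] = color + rng.normal(0.0, cfg.noise_sd, size=(int(blob.sum()), 3))
    for cx, cy, ax, ay, phi in distractor_specs:
        blob = _blob_mask((h, w), cx, cy, ax, ay, phi, cfg.irregularity, rng)
        color = np.array(cfg.distractor_rgb) + rng.normal(0.0, 6.0, size=3)
        image[blob] = color + rng.normal(0.0, cfg.noise_sd, size=(int(blob.sum()), 3))

    image = np.clip(image, 0, 255).astype(np.uint8)

    components = extract_components(mask, min_area=1)
    if len(components) != len(mitosis_specs):  # pragma: no cover - guarded by separation
        raise RuntimeError("mitosis blobs merged despite separation constraint")
    boxes = [min_bounding_rect(comp) for comp in components]
    weak_labels = []
    for comp, box in zip(components, boxes):
        cx, cy = comp[:, 0].mean(), comp[:, 1].mean()
        if cfg.centroid_jitter_sd > 0:
            cx += rng.normal(0.0, cfg.centroid_jitter_sd)
            cy += rng.normal(0.0, cfg.centroid_jitter_sd)
        # keep the label on its component (centroids of concave blobs and
        # jittered points can stray): snap to the nearest component pixel
        x = int(round(cx))
        y = int(round(cy))
        if not mask[min(max(y, 0), h - 1), min(max(x, 0), w - 1)]:
            d2 = (comp[:, 0] - cx) ** 2 + (comp[:, 1] - cy) ** 2
            x, y = (int(v) for v in comp[int(np.argmin(d2))])
        weak_labels.append(WeakLabel(x=x, y=y))
    return SynthTile(
        image=image, mask=mask, boxes=boxes, weak_labels=weak_labels,
        microns_per_pixel=cfg.microns_per_pixel,
    )


def _child_seed(base: int, index: int) -> int:
    # deterministic per-tile seed fan-out, kept below 2**31
    return (base * 100003 + 7919 * index + 1) % (2 ** 31)


def generate_dataset(
    n_tiles: int,
    cfg: SynthConfig,
    split: float,
    out_dir: str | Path,
) -> dict:
    """Write a seeded train/val dataset to disk and return its manifest.

    Layout under ``out_dir``: ``images/<stem>.png``, ``masks/<stem>.png``
    (0/255), ``weak_labels/<stem>.csv`` (``x,y`` rows), ``boxes/<stem>.csv``
    (``x0,y0,x1,y1,positive``) and ``manifest.json``.  The train/val
    split is a seeded disjoint partition with ``round(split * n_tiles)``
    training tiles.
    """
    from mitodet import io as mio

    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if not (0.0 < split < 1.0):
        raise ValueError("split must lie in (0, 1)")
    out = Path(out_dir)
    for sub in ("images", "masks", "weak_labels", "boxes"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    stems = [f"tile_{i:04d}" for i in range(n_tiles)]
    for i, stem in enumerate(stems):
        tile = generate_tile(replace(cfg, seed=_child_seed(cfg.seed, i)))
        iio.imwrite(out / "images" / f"{stem}.png", tile.image)
        iio.imwrite(out / "masks" / f"{stem}.png",
                    (tile.mask.astype(np.uint8) * 255))
        mio.write_weak_labels(out / "weak_labels" / f"{stem}.csv", tile.weak_labels)
        from mitodet.labelgen import LabeledBox
        labeled = [LabeledBox(box=b, positive=True, matched_weak_label=p)
                   for b, p in zip(tile.boxes, tile.weak_labels)]
        mio.write_boxes(out / "boxes" / f"{stem}.csv", labeled)

    order = np.random.default_rng(_child_seed(cfg.seed, n_tiles)).permutation(n_tiles)
    n_train = int(round(split * n_tiles))
    train = sorted(stems[i] for i in order[:n_train])
    val = sorted(stems[i] for i in order[n_train:])
    manifest = {
        "seed": cfg.seed,
        "split": split,
        "tile_size": list(cfg.tile_size),
        "microns_per_pixel": cfg.microns_per_pixel,
        "train": train,
        "val": val,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
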