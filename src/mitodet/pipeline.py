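"""End-to-end pipeline: synth -> train-seg -> gen-labels -> train-det ->
detect -> evaluate, with one global seed fanned out to fixed per-stage
seeds so each stage is independently reproducible.

The YAML pipeline config mirrors the per-module configuration
dataclasses; every block is validated at construction, before any stage
runs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from mitodet import io as mio
from mitodet.detector import DetectorConfig, detect, train_detector
from mitodet.evalprotocol import ConfusionCounts, ResolutionSpec, compute_metrics, match_detections
from mitodet.labelgen import generate_strong_labels
from mitodet.segnet import SegNetConfig, TrainConfig, predict_probmap, train_segmentation
from mitodet.synthdata import SynthConfig, generate_tile
from mitodet.io import stage_seed

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration of the full two-phase pipeline."""

    seed: int = 0
    n_train_tiles: int = 16
    n_val_tiles: int = 4
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(
        n_mitoses_range=(2, 4)))
    segnet: SegNetConfig = field(default_factory=lambda: SegNetConfig(
        levels=2, channels=(8, 16)))
    seg_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=80, lr_end=1e-4))
    labelgen_threshold: float = 0.5
    labelgen_min_area: int = 5
    detector: DetectorConfig = field(default_factory=lambda: DetectorConfig(
        warp_size=32,
        proposal_params={"sizes": (8, 12, 16), "strides": (4, 4, 4)}))
    resolution: ResolutionSpec = field(default_factory=lambda: ResolutionSpec(0.25))

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive every per-stage seed from one global seed."""
        return replace(
            self,
            seed=seed,
            synth=replace(self.synth, seed=stage_seed(seed, "synth")),
            segnet=replace(self.segnet, seed=stage_seed(seed, "segnet")),
            seg_train=replace(self.seg_train, seed=stage_seed(seed, "seg_train")),
            detector=replace(self.detector, seed=stage_seed(seed, "detector")),
        )


def _build(cls, block: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    for key in ("channels", "tile_size", "mitosis_axes_range", "feature_channels",
                "background_rgb", "mitosis_rgb", "distractor_rgb"):
        if key in block and isinstance(block[key], list):
            block[key] = tuple(block[key])
    return cls(**block)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for scalar in ("seed", "n_train_tiles", "n_val_tiles",
                   "labelgen_threshold", "labelgen_min_area"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    mapping = {
        "synth": SynthConfig, "segnet": SegNetConfig, "seg_train": TrainConfig,
        "detector": DetectorConfig, "resolution": ResolutionSpec,
    }
    for name, cls in mapping.items():
        if name in raw:
            kwargs[name] = _build(cls, dict(raw[name]))
    cfg = PipelineConfig(**kwargs)
    if "seed" in raw:
        cfg = cfg.with_seed(raw["seed"])
    return cfg


def run_pipeline(cfg: PipelineConfig, workdir: str | Path | None = None,
                 log=print) -> dict:
    """Run the full two-phase flow on synthetic data and score it.

    Generates seeded train/val tiles, trains the segmentation network on
    the training tiles' pixel masks, converts predicted probability maps
    plus weak labels into bounding-box strong labels, trains the
    detector on those boxes, detects on the validation tiles and scores
    them against the validation weak labels (pooled counts).  Returns a
    dict with the metrics, counts and per-stage timings; artifacts are
    written under ``workdir`` when given.
    """
    cfg = cfg.with_seed(cfg.seed)
    out = Path(workdir) if workdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)
            log(f"[{name}] seed={cfg.seed} {timings[name]:.1f}s")
        return done

    # -- synth ---------------------------------------------------------
    end = stage("synth")
    from mitodet.synthdata import _child_seed
    tiles = []
    for i in range(cfg.n_train_tiles + cfg.n_val_tiles):
        tiles.append(generate_tile(replace(cfg.synth, seed=_child_seed(cfg.synth.seed, i))))
    train_tiles = tiles[:cfg.n_train_tiles]
    val_tiles = tiles[cfg.n_train_tiles:]
    end()

    # -- phase 1: segmentation + label generation ----------------------
    end = stage("train-seg")
    model, seg_history = train_segmentation(
        [t.image for t in train_tiles], [t.mask.astype(np.intp) for t in train_tiles],
        cfg.seg_train, cfg.segnet,
    )
    end()

    end = stage("gen-labels")
    strong_labels = []
    n_unmatched = 0
    for t in train_tiles:
        probmap = predict_probmap(model, t.image)
        labeled, unmatched = generate_strong_labels(
            probmap, t.weak_labels,
            threshold=cfg.labelgen_threshold, min_area=cfg.labelgen_min_area,
        )
        strong_labels.append(labeled)
        n_unmatched += len(unmatched)
    end()

    # -- phase 2: detector ---------------------------------------------
    end = stage("train-det")
    det_model, det_losses = train_detector(
        [t.image for t in train_tiles], strong_labels, cfg.detector)
    end()

    end = stage("detect+evaluate")
    counts = ConfusionCounts(0, 0, 0)
    per_tile = []
    for t in val_tiles:
        detections = detect(det_model, t.image)
        c, _ = match_detections(detections, t.weak_labels, cfg.resolution)
        counts = counts + c
        per_tile.append({"tp": c.tp, "fp": c.fp, "fn": c.fn})
    metrics = compute_metrics(counts)
    end()

    result = {
        "seed": cfg.seed,
        "n_train_tiles": cfg.n_train_tiles,
        "n_val_tiles": cfg.n_val_tiles,
        "n_gt_val": sum(len(t.weak_labels) for t in val_tiles),
        "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
        "precision": metrics.precision, "recall": metrics.recall, "f1": metrics.f1,
        "seg_loss_first": seg_history[0], "seg_loss_last": seg_history[-1],
        "det_loss_first": det_losses[0], "det_loss_last": det_losses[-1],
        "unmatched_weak_labels": n_unmatched,
        "per_tile": per_tile,
        "timings_s": timings,
    }
    if out is not None:
        (out / "metrics.json").write_text(json.dumps(result, indent=2, sort_keys=True))
        from mitodet.segnet import save_model
        save_model(model, out / "segnet.npz")
    return result
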