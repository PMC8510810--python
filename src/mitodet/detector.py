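"""R-CNN-style mitosis detector trained on generated strong labels.

The four-step routine: region-proposal generation (selective search, or
a deterministic multi-scale sliding window for fast runs), CNN feature
extraction on fixed-size warped crops, SVM region classification, and
bounding-box regression.  Training minibatches follow the original
R-CNN recipe of 32 positive plus 96 negative regions.

Proposals overlapping a ground-truth box at IoU >= ``pos_iou`` are
positives, those below ``neg_iou`` negatives, the rest are discarded.
At inference, scored and regressed boxes above the confidence threshold
pass through greedy non-maximum suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.segmentation import felzenszwalb
from skimage.transform import resize
from sklearn.linear_model import Ridge
from sklearn.svm import LinearSVC

from mitodet import _nn
from mitodet._nn import Adam, BatchNorm2d, Conv2d, Linear, MaxPool2d, ReLU, Sequential
from mitodet.labelgen import BoundingBox, LabeledBox

__all__ = [
    "RegionProposal", "Detection", "MinibatchSpec", "DetectorConfig",
    "DetectorModel", "iou", "propose_regions", "label_proposals",
    "sample_minibatch", "bbox_regression_targets", "apply_regression",
    "nms", "train_detector", "detect",
]


@dataclass(frozen=True)
class RegionProposal:
    """A candidate box, optionally carrying a proposal score."""

    box: BoundingBox
    score: float | None = None


@dataclass(frozen=True)
class Detection:
    """A final detector output: box plus confidence in [0, 1]."""

    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class MinibatchSpec:
    """The 32-positive / 96-negative minibatch composition."""

    n_pos: int = 32
    n_neg: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("minibatch quotas must be positive")

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class DetectorConfig:
    """Detector hyperparameters; all unstated values are config-exposed."""

    warp_size: int = 64
    pos_iou: float = 0.5
    neg_iou: float = 0.3
    nms_iou: float = 0.3
    score_threshold: float = 0.5
    proposal_method: str = "sliding_window"
    proposal_params: dict | None = None
    feature_channels: tuple[int, int, int] = (8, 16, 32)
    classifier: str = "svm"  # or "softmax"
    use_bbox_regression: bool = True
    n_iters: int = 60
    lr: float = 1e-3
    max_neg_per_tile: int = 150
    minibatch: MinibatchSpec = field(default_factory=MinibatchSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pos_iou > self.neg_iou:
            raise ValueError("require pos_iou > neg_iou")
        if self.classifier not in ("svm", "softmax"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes; symmetric, in [0, 1]."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def _clip_box(x0: float, y0: float, x1: float, y1: float,
              h: int, w: int) -> BoundingBox | None:
    x0c, y0c = max(0.0, x0), max(0.0, y0)
    x1c, y1c = min(float(w), x1), min(float(h), y1)
    if x1c - x0c < 1.0 or y1c - y0c < 1.0:
        return None
    return BoundingBox(x0c, y0c, x1c, y1c)


def _sliding_window_proposals(h: int, w: int, params: dict) -> list[RegionProposal]:
    sizes = params.get("sizes", (8, 12, 16, 24))
    strides = params.get("strides", None)
    if "window" in params:  # single-scale shorthand
        sizes = (params["window"],)
        strides = (params.get("stride", params["window"] // 2),)
    if strides is None:
        strides = tuple(max(1, s // 2) for s in sizes)
    proposals = []
    for size, stride in zip(sizes, strides):
        if size > min(h, w):
            continue
        for y0 in range(0, h - size + 1, stride):
            for x0 in range(0, w - size + 1, stride):
                proposals.append(RegionProposal(BoundingBox(x0, y0, x0 + size, y0 + size)))
    return proposals


def _region_histogram(img: np.ndarray, region_mask: np.ndarray, bins: int = 8) -> np.ndarray:
    hist = []
    for ch in range(img.shape[2]):
        counts, _ = np.histogram(img[..., ch][region_mask], bins=bins, range=(0.0, 1.0))
        hist.append(counts)
    h = np.concatenate(hist).astype(np.float64)
    s = h.sum()
    return h / s if s else h


def _selective_search_proposals(img: np.ndarray, params: dict) -> list[RegionProposal]:
    """Graph-based over-segmentation + greedy hierarchical region merging.

    Similarity between adjacent regions combines color-histogram
    intersection, a small-size preference and fill (how tightly the
    union bounding box wraps the pair) — the classic selective-search
    ingredients minus the texture channel, which contributes little at
    mitosis scale.
    """
    scale = params.get("scale", 50)
    sigma = params.get("sigma", 0.8)
    min_size = params.get("min_size", 5)
    max_proposals = params.get("max_proposals", 200)

    imgf = img.astype(np.float64) / 255.0 if img.dtype == np.uint8 else np.asarray(img, float)
    seg = felzenszwalb(imgf, scale=scale, sigma=sigma, min_size=min_size)
    h, w = seg.shape
    labels = np.unique(seg)
    regions: dict[int, dict] = {}
    for lab in labels:
        m = seg == lab
        ys, xs = np.nonzero(m)
        regions[int(lab)] = {
            "size": int(m.sum()),
            "bbox": (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1),
            "hist": _region_histogram(imgf, m),
        }
    # adjacency from horizontal/vertical neighbors
    pairs = set()
    a, b = seg[:, :-1], seg[:, 1:]
    for p, q in zip(a[a != b].ravel(), b[a != b].ravel()):
        pairs.add((int(min(p, q)), int(max(p, q))))
    a, b = seg[:-1, :], seg[1:, :]
    for p, q in zip(a[a != b].ravel(), b[a != b].ravel()):
        pairs.add((int(min(p, q)), int(max(p, q))))

    img_area = float(h * w)

    def similarity(ri: dict, rj: dict) -> float:
        s_color = np.minimum(ri["hist"], rj["hist"]).sum()
        s_size = 1.0 - (ri["size"] + rj["size"]) / img_area
        bx0 = min(ri["bbox"][0], rj["bbox"][0]); by0 = min(ri["bbox"][1], rj["bbox"][1])
        bx1 = max(ri["bbox"][2], rj["bbox"][2]); by1 = max(ri["bbox"][3], rj["bbox"][3])
        bb_area = (bx1 - bx0) * (by1 - by0)
        s_fill = 1.0 - (bb_area - ri["size"] - rj["size"]) / img_area
        return s_color + s_size + s_fill

    boxes: list[tuple[int, int, int, int]] = [r["bbox"] for r in regions.values()]
    sims = {(i, j): similarity(regions[i], regions[j]) for i, j in pairs}
    next_label = int(labels.max()) + 1
    while sims:
        (i, j) = max(sims, key=lambda k: (sims[k], -k[0], -k[1]))
        ri, rj = regions.pop(i), regions.pop(j)
        merged = {
            "size": ri["size"] + rj["size"],
            "bbox": (
                min(ri["bbox"][0], rj["bbox"][0]), min(ri["bbox"][1], rj["bbox"][1]),
                max(ri["bbox"][2], rj["bbox"][2]), max(ri["bbox"][3], rj["bbox"][3]),
            ),
            "hist": (ri["hist"] * ri["size"] + rj["hist"] * rj["size"])
                    / (ri["size"] + rj["size"]),
        }
        regions[next_label] = merged
        boxes.append(merged["bbox"])
        neighbors = {
            (min(k, next_label), max(k, next_label))
            for (p, q) in sims if p in (i, j) or q in (i, j)
            for k in (p, q) if k not in (i, j)
        }
        sims = {k: v for k, v in sims.items() if i not in k and j not in k}
        for p, q in neighbors:
            sims[(p, q)] = similarity(regions[p], regions[q])
        next_label += 1

    seen = set()
    proposals = []
    for bx in boxes:
        if bx not in seen:
            seen.add(bx)
            proposals.append(RegionProposal(BoundingBox(*bx)))
        if len(proposals) >= max_proposals:
            break
    return proposals


def propose_regions(tile: np.ndarray, method: str = "sliding_window",
                    params: dict | None = None) -> list[RegionProposal]:
    """Generate candidate boxes for one RGB tile, clipped to its bounds.

    ``method`` is ``"selective_search"`` (hierarchical region merging
    over a graph-based over-segmentation) or ``"sliding_window"``
    (multi-scale square windows; deterministic and fast, the default in
    small-scale runs).
    """
    img = np.asarray(getattr(tile, "image", tile))
    h, w = img.shape[:2]
    params = dict(params or {})
    if method == "sliding_window":
        return _sliding_window_proposals(h, w, params)
    if method == "selective_search":
        return _selective_search_proposals(img, params)
    raise ValueError(f"unknown proposal method {method!r}")


def label_proposals(
    proposals: list[RegionProposal],
    gt_boxes: list[BoundingBox | LabeledBox],
    pos_iou: float = 0.5,
    neg_iou: float = 0.3,
) -> tuple[list[tuple[RegionProposal, BoundingBox]], list[RegionProposal]]:
    """Partition proposals into positives (with their best gt) and negatives.

    A proposal is positive when its maximum IoU against any ground-truth
    box reaches ``pos_iou``, negative when below ``neg_iou``; the
    in-between band is discarded as ambiguous.  Only positive LabeledBox
    entries count as ground truth.
    """
    if not pos_iou > neg_iou:
        raise ValueError("require pos_iou > neg_iou")
    gts = []
    for g in gt_boxes:
        if isinstance(g, LabeledBox):
            if g.positive:
                gts.append(g.box)
        else:
            gts.append(g)
    positives, negatives = [], []
    for prop in proposals:
        best_iou, best_gt = 0.0, None
        for g in gts:
            v = iou(prop.box, g)
            if v > best_iou:
                best_iou, best_gt = v, g
        if best_iou >= pos_iou:
            positives.append((prop, best_gt))
        elif best_iou < neg_iou:
            negatives.append(prop)
    return positives, negatives


def sample_minibatch(positives: list, negatives: list, spec: MinibatchSpec,
                     rng: np.random.Generator | None = None) -> tuple[list, list]:
    """Draw exactly ``n_pos`` positives and ``n_neg`` negatives.

    Pools smaller than their quota are sampled with replacement, larger
    ones without.  With no explicit ``rng`` the draw is a pure function
    of ``spec.seed``.
    """
    if len(positives) == 0:
        raise ValueError("cannot sample: positive pool is empty")
    if len(negatives) == 0:
        raise ValueError("cannot sample: negative pool is empty")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    def draw(pool: list, n: int) -> list:
        idx = rng.choice(len(pool), size=n, replace=len(pool) < n)
        return [pool[i] for i in idx]

    return draw(positives, spec.n_pos), draw(negatives, spec.n_neg)


def bbox_regression_targets(proposal: BoundingBox, gt: BoundingBox) -> np.ndarray:
    """R-CNN center/log-size offsets (dx, dy, dw, dh) from proposal to gt."""
    px, py = proposal.center()
    pw, ph = proposal.width, proposal.height
    if pw <= 0 or ph <= 0:
        raise ValueError("zero-size proposal")
    gx, gy = gt.center()
    return np.array([
        (gx - px) / pw, (gy - py) / ph,
        math.log(gt.width / pw), math.log(gt.height / ph),
    ])


def apply_regression(proposal: BoundingBox, targets: np.ndarray) -> BoundingBox:
    """Inverse of :func:`bbox_regression_targets`; exact round trip."""
    dx, dy, dw, dh = (float(t) for t in targets)
    px, py = proposal.center()
    gx = px + dx * proposal.width
    gy = py + dy * proposal.height
    gw = proposal.width * math.exp(dw)
    gh = proposal.height * math.exp(dh)
    return BoundingBox(gx - gw / 2, gy - gh / 2, gx + gw / 2, gy + gh / 2)


def nms(boxes: list[BoundingBox], scores: list[float], iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept: list[int] = []
    for i in order:
        if all(iou(boxes[i], boxes[j]) <= iou_threshold for j in kept):
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# feature CNN + training
# ---------------------------------------------------------------------------

def _build_feature_cnn(cfg: DetectorConfig, rng: np.random.Generator) -> tuple[Sequential, int]:
    layers: list[_nn.Layer] = []
    in_ch = 3
    side = cfg.warp_size
    for out_ch in cfg.feature_channels:
        layers += [Conv2d(in_ch, out_ch, 3, rng), BatchNorm2d(out_ch), ReLU(), MaxPool2d()]
        in_ch = out_ch
        side //= 2
    feat_dim = in_ch * side * side
    return Sequential(layers), feat_dim


def _warp_crop(img: np.ndarray, box: BoundingBox, warp_size: int) -> np.ndarray:
    """Clip a box to the image, crop, and warp to (warp_size, warp_size, 3)."""
    h, w = img.shape[:2]
    x0 = min(max(int(math.floor(box.x0)), 0), w - 1)
    y0 = min(max(int(math.floor(box.y0)), 0), h - 1)
    x1 = min(max(int(math.ceil(box.x1)), x0 + 1), w)
    y1 = min(max(int(math.ceil(box.y1)), y0 + 1), h)
    crop = img[y0:y1, x0:x1]
    if crop.dtype == np.uint8:
        crop = crop.astype(np.float64) / 255.0
    return resize(crop, (warp_size, warp_size), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


@dataclass
class DetectorModel:
    """Trained detector: feature CNN + region classifier + bbox regressor."""

    cfg: DetectorConfig
    cnn: Sequential
    feat_dim: int
    head: Linear
    svm: LinearSVC | None = None
    bbox_reg: Ridge | None = None

    def features(self, crops: np.ndarray) -> np.ndarray:
        """(N, warp, warp, 3) float crops -> (N, feat_dim) frozen features."""
        x = crops.transpose(0, 3, 1, 2)
        out = self.cnn.forward(x, train=False)
        return out.reshape(out.shape[0], -1)

    def score(self, feats: np.ndarray) -> np.ndarray:
        """Mitosis confidence in [0, 1] for each feature row."""
        if self.cfg.classifier == "svm":
            margin = self.svm.decision_function(feats)
            return 1.0 / (1.0 + np.exp(-margin))
        logits = self.head.forward(feats, train=False)
        return _nn.softmax(logits, axis=-1)[:, 1]


def _gather_pools(tiles, labeled_boxes, cfg: DetectorConfig):
    """Collect warped positive/negative crops and regression targets."""
    rng = np.random.default_rng(cfg.seed + 1)
    pos_crops, pos_targets, neg_crops = [], [], []
    for img_in, gt in zip(tiles, labeled_boxes):
        img = np.asarray(getattr(img_in, "image", img_in))
        gt_pos = [g.box if isinstance(g, LabeledBox) else g
                  for g in gt
                  if not isinstance(g, LabeledBox) or g.positive]
        proposals = propose_regions(img, cfg.proposal_method, cfg.proposal_params)
        # ground-truth boxes join the proposal set, as in R-CNN training
        proposals = proposals + [RegionProposal(b) for b in gt_pos]
        pos, neg = label_proposals(proposals, gt_pos, cfg.pos_iou, cfg.neg_iou)
        if len(neg) > cfg.max_neg_per_tile:
            idx = rng.choice(len(neg), size=cfg.max_neg_per_tile, replace=False)
            neg = [neg[i] for i in idx]
        for prop, g in pos:
            pos_crops.append(_warp_crop(img, prop.box, cfg.warp_size))
            pos_targets.append(bbox_regression_targets(prop.box, g))
        for prop in neg:
            neg_crops.append(_warp_crop(img, prop.box, cfg.warp_size))
    return pos_crops, pos_targets, neg_crops


def train_detector(tiles: list, labeled_boxes: list, cfg: DetectorConfig | None = None,
                   ) -> tuple[DetectorModel, list[float]]:
    """Train the phase-2 detector on tiles with generated strong labels.

    Returns the model and the per-iteration classification loss.  The
    feature CNN is optimised with Adam on 32/96 minibatches through a
    softmax head; the final region classifier is a linear SVM fitted on
    the frozen features (or the softmax head itself when
    ``cfg.classifier == "softmax"``), and a ridge regressor maps
    positive-region features to box offsets.
    """
    cfg = cfg or DetectorConfig()
    if len(tiles) == 0 or len(tiles) != len(labeled_boxes):
        raise ValueError("need matching non-empty tile and label lists")
    pos_crops, pos_targets, neg_crops = _gather_pools(tiles, labeled_boxes, cfg)
    if not pos_crops:
        raise ValueError("no positive boxes anywhere in the training data")
    if not neg_crops:
        raise ValueError("no negative regions found in the training data")

    rng = np.random.default_rng(cfg.seed)
    cnn, feat_dim = _build_feature_cnn(cfg, rng)
    head = Linear(feat_dim, 2, rng)
    opt = Adam(cnn.params() + head.params())
    spec = cfg.minibatch
    pos_arr = np.stack(pos_crops)
    neg_arr = np.stack(neg_crops)
    losses: list[float] = []
    labels = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    for _ in range(cfg.n_iters):
        pi = rng.choice(len(pos_arr), size=spec.n_pos, replace=len(pos_arr) < spec.n_pos)
        ni = rng.choice(len(neg_arr), size=spec.n_neg, replace=len(neg_arr) < spec.n_neg)
        batch = np.concatenate([pos_arr[pi], neg_arr[ni]]).transpose(0, 3, 1, 2)
        feats = cnn.forward(batch, train=True)
        flat = feats.reshape(feats.shape[0], -1)
        logits = head.forward(flat, train=True)
        loss, grad = _nn.softmax_cross_entropy(logits, labels, axis=-1)
        opt.zero_grad()
        gflat = head.backward(grad)
        cnn.backward(gflat.reshape(feats.shape))
        opt.step(cfg.lr)
        losses.append(loss)

    model = DetectorModel(cfg=cfg, cnn=cnn, feat_dim=feat_dim, head=head)
    all_feats = model.features(np.concatenate([pos_arr, neg_arr]))
    pos_feats = all_feats[:len(pos_arr)]
    if cfg.classifier == "svm":
        y = np.array([1] * len(pos_arr) + [0] * len(neg_arr))
        svm = LinearSVC(C=1.0, dual=False, random_state=cfg.seed, max_iter=5000)
        svm.fit(all_feats, y)
        model.svm = svm
    if cfg.use_bbox_regression:
        reg = Ridge(alpha=1.0, random_state=cfg.seed)
        reg.fit(pos_feats, np.stack(pos_targets))
        model.bbox_reg = reg
    return model, losses


def save_detector(model: DetectorModel, path) -> None:
    """Serialise the detector (CNN weights, BN stats, head, SVM, regressor)."""
    import json

    cfg = model.cfg
    meta = {
        "warp_size": cfg.warp_size, "pos_iou": cfg.pos_iou, "neg_iou": cfg.neg_iou,
        "nms_iou": cfg.nms_iou, "score_threshold": cfg.score_threshold,
        "proposal_method": cfg.proposal_method, "proposal_params": cfg.proposal_params,
        "feature_channels": list(cfg.feature_channels), "classifier": cfg.classifier,
        "use_bbox_regression": cfg.use_bbox_regression, "n_iters": cfg.n_iters,
        "lr": cfg.lr, "max_neg_per_tile": cfg.max_neg_per_tile, "seed": cfg.seed,
    }
    arrays = {}
    params = model.cnn.params() + model.head.params()
    for i, p in enumerate(params):
        arrays[f"p_{i}"] = p.value
    bn_arrays = []
    for layer in model.cnn.layers:
        if isinstance(layer, BatchNorm2d):
            bn_arrays += [layer.running_mean, layer.running_var]
    for i, a in enumerate(bn_arrays):
        arrays[f"bn_{i}"] = a
    if model.svm is not None:
        arrays["svm_coef"] = model.svm.coef_
        arrays["svm_intercept"] = model.svm.intercept_
    if model.bbox_reg is not None:
        arrays["reg_coef"] = model.bbox_reg.coef_
        arrays["reg_intercept"] = model.bbox_reg.intercept_
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_detector(path) -> DetectorModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        meta["feature_channels"] = tuple(meta["feature_channels"])
        cfg = DetectorConfig(**meta)
        rng = np.random.default_rng(cfg.seed)
        cnn, feat_dim = _build_feature_cnn(cfg, rng)
        head = Linear(feat_dim, 2, rng)
        model = DetectorModel(cfg=cfg, cnn=cnn, feat_dim=feat_dim, head=head)
        for i, p in enumerate(cnn.params() + head.params()):
            p.value[...] = data[f"p_{i}"]
        i = 0
        for layer in cnn.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = data[f"bn_{i}"]
                layer.running_var[...] = data[f"bn_{i + 1}"]
                i += 2
        if "svm_coef" in data:
            svm = LinearSVC(C=1.0, dual=False, random_state=cfg.seed)
            svm.coef_ = data["svm_coef"]
            svm.intercept_ = data["svm_intercept"]
            svm.classes_ = np.array([0, 1])
            model.svm = svm
        if "reg_coef" in data:
            reg = Ridge(alpha=1.0)
            reg.coef_ = data["reg_coef"]
            reg.intercept_ = data["reg_intercept"]
            model.bbox_reg = reg
    return model


def detect(model: DetectorModel, tile: np.ndarray,
           score_threshold: float | None = None,
           nms_iou: float | None = None) -> list[Detection]:
    """Run the trained detector on one tile.

    Proposals are scored, boxes regressed (when the model carries a
    regressor), thresholded, and filtered by greedy NMS; the result is
    sorted by descending confidence.
    """
    cfg = model.cfg
    thr = cfg.score_threshold if score_threshold is None else score_threshold
    nthr = cfg.nms_iou if nms_iou is None else nms_iou
    img = np.asarray(getattr(tile, "image", tile))
    h, w = img.shape[:2]
    proposals = propose_regions(img, cfg.proposal_method, cfg.proposal_params)
    if not proposals:
        return []
    crops = np.stack([_warp_crop(img, p.box, cfg.warp_size) for p in proposals])
    feats = model.features(crops)
    scores = model.score(feats)
    keep = [i for i in range(len(proposals)) if scores[i] >= thr]
    if not keep:
        return []
    boxes = []
    confs = []
    if model.bbox_reg is not None:
        offsets = model.bbox_reg.predict(feats[keep])
    else:
        offsets = np.zeros((len(keep), 4))
    for row, i in enumerate(keep):
        refined = apply_regression(proposals[i].box, offsets[row])
        clipped = _clip_box(refined.x0, refined.y0, refined.x1, refined.y1, h, w)
        if clipped is not None:
            boxes.append(clipped)
            confs.append(float(scores[i]))
    kept = nms(boxes, confs, nthr)
    return [Detection(box=boxes[i], confidence=confs[i]) for i in kept]
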