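"""Detector: IoU, proposals, minibatch recipe, regression, NMS, training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitodet.detector import (
    Detection,
    DetectorConfig,
    MinibatchSpec,
    RegionProposal,
    apply_regression,
    bbox_regression_targets,
    detect,
    iou,
    label_proposals,
    load_detector,
    nms,
    propose_regions,
    sample_minibatch,
    save_detector,
    train_detector,
)
from mitodet.labelgen import BoundingBox, LabeledBox, WeakLabel


def pixel_count_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Count covered integer pixels of two integer boxes directly."""
    pa = {(x, y) for x in range(int(a.x0), int(a.x1)) for y in range(int(a.y0), int(a.y1))}
    pb = {(x, y) for x in range(int(b.x0), int(b.x1)) for y in range(int(b.y0), int(b.y1))}
    return len(pa & pb) / len(pa | pb)


# -- IoU --------------------------------------------------------------------

def test_iou_identical_and_disjoint():
    a = BoundingBox(0, 0, 4, 4)
    assert iou(a, a) == 1.0
    assert iou(a, BoundingBox(10, 10, 12, 12)) == 0.0


def test_iou_overlap_matches_pixel_counting():
    a, b = BoundingBox(0, 0, 4, 4), BoundingBox(2, 2, 6, 6)
    assert iou(a, b) == pytest.approx(1 / 7)
    assert iou(a, b) == pytest.approx(pixel_count_iou(a, b))
    assert iou(a, b) == iou(b, a)


def test_iou_random_boxes_match_pixel_oracle(rng):
    for _ in range(20):
        x0, y0, x2, y2 = rng.integers(0, 10, size=4)
        a = BoundingBox(x0, y0, x0 + int(rng.integers(1, 8)), y0 + int(rng.integers(1, 8)))
        b = BoundingBox(x2, y2, x2 + int(rng.integers(1, 8)), y2 + int(rng.integers(1, 8)))
        assert iou(a, b) == pytest.approx(pixel_count_iou(a, b))


# -- proposals --------------------------------------------------------------

def test_sliding_window_count_closed_form():
    tile = np.zeros((32, 32, 3), dtype=np.uint8)
    props = propose_regions(tile, "sliding_window", {"window": 16, "stride": 8})
    # ((32-16)/8 + 1)^2 = 9 fully-inside windows
    assert len(props) == 9
    for p in props:
        assert 0 <= p.box.x0 and p.box.x1 <= 32 and 0 <= p.box.y0 and p.box.y1 <= 32


def test_selective_search_capped_and_deterministic(synth_tiles):
    img = synth_tiles[0].image
    props1 = propose_regions(img, "selective_search", {"max_proposals": 50})
    props2 = propose_regions(img, "selective_search", {"max_proposals": 50})
    assert 0 < len(props1) <= 50
    assert props1 == props2
    h, w = img.shape[:2]
    for p in props1:
        assert 0 <= p.box.x0 < p.box.x1 <= w and 0 <= p.box.y0 < p.box.y1 <= h


def test_selective_search_covers_mitoses(synth_tiles):
    """At least one proposal overlaps each true mitosis reasonably well."""
    tile = synth_tiles[0]
    props = propose_regions(tile.image, "selective_search", {"max_proposals": 200})
    for gt in tile.boxes:
        assert max(iou(p.box, gt) for p in props) > 0.3


def test_selective_search_blank_tile_respects_cap():
    blank = np.full((32, 32, 3), 200, dtype=np.uint8)
    props = propose_regions(blank, "selective_search", {"max_proposals": 10})
    assert 1 <= len(props) <= 10


def test_unknown_method_raises():
    with pytest.raises(ValueError, match="unknown proposal method"):
        propose_regions(np.zeros((16, 16, 3)), "magic")


# -- proposal labeling ------------------------------------------------------

def test_label_proposals_examples():
    gt = [BoundingBox(10, 10, 20, 20)]
    exact = RegionProposal(BoundingBox(10, 10, 20, 20))
    far = RegionProposal(BoundingBox(40, 40, 50, 50))
    pos, neg = label_proposals([exact, far], gt)
    assert pos == [(exact, gt[0])] and neg == [far]


def test_label_proposals_matches_max_iou_oracle(rng):
    gts = [BoundingBox(5, 5, 15, 15), BoundingBox(20, 20, 28, 30)]
    proposals = []
    for _ in range(10):
        x0, y0 = rng.integers(0, 24, size=2)
        proposals.append(RegionProposal(BoundingBox(
            x0, y0, x0 + int(rng.integers(4, 12)), y0 + int(rng.integers(4, 12)))))
    pos, neg = label_proposals(proposals, gts, pos_iou=0.5, neg_iou=0.3)
    for p in proposals:
        best = max(iou(p.box, g) for g in gts)
        if best >= 0.5:
            assert any(pp is p for pp, _ in pos)
        elif best < 0.3:
            assert any(pp is p for pp in neg)
        else:
            assert all(pp is not p for pp, _ in pos)
            assert all(pp is not p for pp in neg)


def test_labeled_boxes_only_positive_count_as_gt():
    pos_box = LabeledBox(BoundingBox(0, 0, 8, 8), True, WeakLabel(4, 4))
    neg_box = LabeledBox(BoundingBox(20, 20, 28, 28), False)
    prop = RegionProposal(BoundingBox(20, 20, 28, 28))
    pos, neg = label_proposals([prop], [pos_box, neg_box])
    assert pos == [] and neg == [prop]


# -- minibatch --------------------------------------------------------------

def test_minibatch_contract_100_pool_configurations():
    """Exactly 32 positives + 96 negatives, whatever the pool sizes."""
    for seed in range(100):
        r = np.random.default_rng(seed)
        n_pos, n_neg = int(r.integers(1, 200)), int(r.integers(1, 600))
        spec = MinibatchSpec(seed=seed)
        pos, neg = sample_minibatch(list(range(n_pos)), list(range(n_neg)), spec)
        assert len(pos) == 32 and len(neg) == 96
        assert set(pos) <= set(range(n_pos)) and set(neg) <= set(range(n_neg))


def test_minibatch_replacement_from_small_pool():
    pos, neg = sample_minibatch([0, 1, 2, 3, 4], list(range(500)), MinibatchSpec(seed=3))
    assert len(pos) == 32 and set(pos) <= {0, 1, 2, 3, 4}
    assert len(set(neg)) == 96  # large pool sampled without replacement


def test_minibatch_deterministic_and_errors():
    spec = MinibatchSpec(seed=11)
    a = sample_minibatch(list(range(50)), list(range(200)), spec)
    b = sample_minibatch(list(range(50)), list(range(200)), spec)
    assert a == b
    with pytest.raises(ValueError, match="positive"):
        sample_minibatch([], [1], spec)
    with pytest.raises(ValueError, match="negative"):
        sample_minibatch([1], [], spec)


# -- bbox regression --------------------------------------------------------

def test_regression_identity_and_doubling():
    p = BoundingBox(0, 0, 10, 10)
    np.testing.assert_allclose(bbox_regression_targets(p, p), 0.0, atol=1e-12)
    t = bbox_regression_targets(p, BoundingBox(0, 0, 20, 20))
    np.testing.assert_allclose(t, [0.5, 0.5, math.log(2), math.log(2)])
    decoded = apply_regression(p, t)
    assert (decoded.x0, decoded.y0, decoded.x1, decoded.y1) == (0, 0, 20, 20)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(2, 20), st.integers(2, 20),
       st.integers(0, 30), st.integers(0, 30), st.integers(2, 20), st.integers(2, 20))
def test_regression_encode_decode_inverse(px, py, pw, ph, gx, gy, gw, gh):
    p = BoundingBox(px, py, px + pw, py + ph)
    g = BoundingBox(gx, gy, gx + gw, gy + gh)
    d = apply_regression(p, bbox_regression_targets(p, g))
    assert abs(d.x0 - g.x0) < 1e-9 and abs(d.y1 - g.y1) < 1e-9


# -- NMS --------------------------------------------------------------------

def test_nms_degenerate_duplicate():
    boxes = [BoundingBox(0, 0, 10, 10), BoundingBox(0, 0, 10, 10)]
    kept = nms(boxes, [0.9, 0.8], 0.3)
    assert kept == [0]


def brute_force_nms(boxes, scores, thr):
    alive = list(range(len(boxes)))
    kept = []
    while alive:
        best = max(alive, key=lambda i: (scores[i], -i))
        kept.append(best)
        alive = [i for i in alive if i != best and iou(boxes[i], boxes[best]) <= thr]
    return kept


def test_nms_matches_exhaustive_oracle(rng):
    for _ in range(20):
        boxes, scores = [], []
        for _ in range(6):
            x0, y0 = rng.integers(0, 20, size=2)
            boxes.append(BoundingBox(x0, y0, x0 + int(rng.integers(4, 12)),
                                     y0 + int(rng.integers(4, 12))))
            scores.append(float(rng.uniform(0, 1)))
        assert nms(boxes, scores, 0.3) == brute_force_nms(boxes, scores, 0.3)


# -- training and detection -------------------------------------------------

def fast_cfg(seed=3, **kw):
    base = dict(
        warp_size=32,
        proposal_params={"sizes": (8, 12, 16), "strides": (4, 4, 4)},
        n_iters=40, seed=seed,
    )
    base.update(kw)
    return DetectorConfig(**base)


@pytest.fixture(scope="module")
def trained_detector(synth_tiles):
    tiles = synth_tiles[:8]
    labels = [
        [LabeledBox(b, True, w) for b, w in zip(t.boxes, t.weak_labels)]
        for t in tiles
    ]
    model, losses = train_detector([t.image for t in tiles], labels, fast_cfg())
    return tiles, model, losses


def test_training_loss_decreases(trained_detector):
    _, _, losses = trained_detector
    assert np.mean(losses[-5:]) < np.mean(losses[:5])


def test_training_is_reproducible(synth_tiles):
    tiles = synth_tiles[:3]
    labels = [
        [LabeledBox(b, True, w) for b, w in zip(t.boxes, t.weak_labels)]
        for t in tiles
    ]
    cfg = fast_cfg(n_iters=5)
    m1, l1 = train_detector([t.image for t in tiles], labels, cfg)
    m2, l2 = train_detector([t.image for t in tiles], labels, cfg)
    assert l1 == l2
    np.testing.assert_array_equal(m1.svm.coef_, m2.svm.coef_)


def test_training_requires_positive_boxes(synth_tiles):
    with pytest.raises(ValueError, match="positive"):
        train_detector([synth_tiles[0].image], [[]], fast_cfg())


def test_detector_recovers_training_tiles(trained_detector):
    """End-to-end on seen tiles: center-distance F1 above the pinned floor."""
    from mitodet.evalprotocol import ResolutionSpec, compute_metrics, match_detections

    tiles, model, _ = trained_detector
    counts = None
    for t in tiles:
        dets = detect(model, t.image)
        c, _ = match_detections(dets, t.weak_labels, ResolutionSpec(0.25))
        counts = c if counts is None else counts + c
    metrics = compute_metrics(counts)
    assert metrics.f1 > 0.7


def test_detect_on_blank_tile_with_high_threshold(trained_detector):
    _, model, _ = trained_detector
    blank = np.full((64, 64, 3), 228, dtype=np.uint8)
    assert detect(model, blank, score_threshold=0.999) == []


def test_detections_sorted_and_valid(trained_detector):
    tiles, model, _ = trained_detector
    dets = detect(model, tiles[0].image)
    confs = [d.confidence for d in dets]
    assert confs == sorted(confs, reverse=True)
    for d in dets:
        assert 0.0 <= d.confidence <= 1.0
        assert 0 <= d.box.x0 < d.box.x1 <= 64


def test_detector_checkpoint_roundtrip(trained_detector, tmp_path):
    tiles, model, _ = trained_detector
    save_detector(model, tmp_path / "det.npz")
    reloaded = load_detector(tmp_path / "det.npz")
    assert detect(model, tiles[0].image) == detect(reloaded, tiles[0].image)
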