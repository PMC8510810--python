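"""Segmentation network: architecture contracts, loss math, training."""

import numpy as np
import pytest

from conftest import dice
from mitodet.segnet import (
    PixelLabelMap,
    ProbabilityMap,
    SegNetConfig,
    TrainConfig,
    build_segnet,
    load_model,
    pixelwise_cross_entropy,
    predict_probmap,
    save_model,
    softmax_pixelwise,
    train_segmentation,
)


def tiny_cfg(**kw):
    base = dict(levels=1, channels=(4,), seed=0)
    base.update(kw)
    return SegNetConfig(**base)


# -- configuration and architecture ----------------------------------------

def test_config_validation():
    with pytest.raises(ValueError, match="levels"):
        SegNetConfig(levels=0, channels=())
    with pytest.raises(ValueError, match="channels"):
        SegNetConfig(levels=2, channels=(8,))
    with pytest.raises(ValueError, match="classes"):
        SegNetConfig(levels=1, channels=(4,), classes=1)
    with pytest.warns(UserWarning, match="4-layer"):
        SegNetConfig(levels=1, channels=(4,), block_depth=3)


def test_output_shape_contract(rng):
    model = build_segnet(tiny_cfg())
    pm = predict_probmap(model, rng.random(size=(8, 8, 3)))
    assert pm.probs.shape == (8, 8, 2)


def test_seeded_init_is_bit_identical():
    a, b = build_segnet(tiny_cfg(seed=5)), build_segnet(tiny_cfg(seed=5))
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)


def test_parameter_count_matches_manual_audit():
    """Hand-count conv (w+b) and BN (gamma+beta) parameters layer by layer."""

    def conv(cin, cout, k):
        return cin * cout * k * k + cout

    def bn(c):
        return 2 * c

    def block(cin, cout, depth=4):
        total = conv(cin, cout, 3) + bn(cout)
        total += (depth - 1) * (conv(cout, cout, 3) + bn(cout))
        return total

    # levels=1, channels=[4], K=2, RGB input
    expected = (
        block(3, 4)            # encoder block at full resolution
        + block(16, 16)        # bottleneck on the 4x4-channel subband stack
        + block(8, 4)          # decoder block on concat(IWT output, skip)
        + conv(4, 2, 1)        # final 1x1 projection
    )
    model = build_segnet(tiny_cfg())
    assert model.num_params() == expected == 10774


@pytest.mark.parametrize("levels,channels", [(1, (4,)), (2, (4, 6)), (3, (4, 4, 4))])
def test_output_shape_equals_input_shape_odd_sizes(levels, channels, rng):
    model = build_segnet(SegNetConfig(levels=levels, channels=channels, seed=1))
    for h, w in [(7, 7), (16, 16), (33, 17), (63, 65)]:
        pm = predict_probmap(model, rng.random(size=(h, w, 3)))
        assert pm.probs.shape == (h, w, 2)
        np.testing.assert_allclose(pm.probs.sum(axis=-1), 1.0, atol=1e-6)


def test_inference_is_deterministic(rng):
    model = build_segnet(tiny_cfg())
    x = rng.random(size=(8, 8, 3))
    assert np.array_equal(predict_probmap(model, x).probs, predict_probmap(model, x).probs)


# -- softmax ----------------------------------------------------------------

def test_softmax_equal_activations_give_half():
    pm = softmax_pixelwise(np.zeros((4, 4, 2)))
    np.testing.assert_allclose(pm.probs, 0.5)


def test_softmax_scalar_example():
    a = np.zeros((1, 1, 2))
    a[0, 0] = (1.0, 0.0)
    # e/(1+e) evaluated directly
    assert softmax_pixelwise(a).probs[0, 0, 0] == pytest.approx(
        np.e / (1 + np.e), abs=1e-4)
    assert softmax_pixelwise(a).probs[0, 0, 0] == pytest.approx(0.7311, abs=1e-4)


def test_softmax_shift_invariance(rng):
    a = rng.normal(size=(3, 3, 4))
    np.testing.assert_allclose(
        softmax_pixelwise(a + 100.0).probs, softmax_pixelwise(a).probs, atol=1e-6)


def test_softmax_rejects_nan():
    a = np.zeros((2, 2, 2))
    a[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        softmax_pixelwise(a)


# -- cross entropy ----------------------------------------------------------

def test_cross_entropy_perfect_prediction_is_zero():
    p = np.zeros((4, 4, 2))
    p[..., 1] = 1.0
    labels = np.ones((4, 4), dtype=int)
    assert pixelwise_cross_entropy(p, labels) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n", [16, 256])
def test_cross_entropy_uniform_closed_form(n):
    side = int(np.sqrt(n))
    p = np.full((side, side, 2), 0.5)
    labels = np.zeros((side, side), dtype=int)
    assert pixelwise_cross_entropy(p, labels) == pytest.approx(n * np.log(2), abs=1e-9)


def test_cross_entropy_matches_elementwise_oracle(rng):
    logits = rng.normal(size=(3, 3, 2))
    pm = softmax_pixelwise(logits)
    labels = rng.integers(0, 2, size=(3, 3))
    oracle = 0.0
    for i in range(3):
        for j in range(3):
            oracle -= np.log(pm.probs[i, j, labels[i, j]])
    assert pixelwise_cross_entropy(pm, labels) == pytest.approx(oracle, abs=1e-10)


def test_loss_softmax_composition_equals_logsumexp(rng):
    logits = rng.normal(size=(4, 4, 3))
    labels = rng.integers(0, 3, size=(4, 4))
    via_softmax = pixelwise_cross_entropy(softmax_pixelwise(logits), labels)
    lse = np.log(np.exp(logits - logits.max(-1, keepdims=True)).sum(-1)) \
        + logits.max(-1)
    direct = float((lse - np.take_along_axis(
        logits, labels[..., None], axis=-1)[..., 0]).sum())
    assert via_softmax == pytest.approx(direct, abs=1e-8)


def test_cross_entropy_rejects_bad_labels():
    p = np.full((2, 2, 2), 0.5)
    with pytest.raises(ValueError, match=r"\[0, 2\)"):
        pixelwise_cross_entropy(p, np.full((2, 2), 2))
    with pytest.raises(ValueError, match="mismatch"):
        pixelwise_cross_entropy(p, np.zeros((3, 3), dtype=int))


def test_probability_map_invariants():
    with pytest.raises(ValueError, match="sum"):
        ProbabilityMap(np.full((2, 2, 2), 0.3))
    with pytest.raises(ValueError, match=r"\[0, 2\)"):
        PixelLabelMap(np.full((2, 2), 5), n_classes=2)


# -- training ---------------------------------------------------------------

def test_training_rejects_bad_data():
    cfg = TrainConfig(epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train_segmentation([], [], cfg, tiny_cfg())
    with pytest.raises(ValueError, match="shape"):
        train_segmentation([np.zeros((8, 8, 3))], [np.zeros((4, 4), dtype=int)],
                           cfg, tiny_cfg())


def test_training_reduces_loss_and_is_reproducible(synth_tiles):
    tiles = [t.image for t in synth_tiles[:8]]
    masks = [t.mask.astype(int) for t in synth_tiles[:8]]
    cfg = TrainConfig(epochs=30, seed=7, lr_end=1e-4)
    net_cfg = SegNetConfig(levels=2, channels=(8, 16), seed=7)
    model, hist = train_segmentation(tiles, masks, cfg, net_cfg)
    assert len(hist) == 30
    assert hist[-1] < hist[0]
    _, hist2 = train_segmentation(tiles, masks, cfg, net_cfg)
    assert hist == hist2


def test_training_reaches_dice_floor(synth_tiles, tmp_path):
    """Desk-scale recovery: foreground Dice > 0.7 on the training tiles."""
    tiles = [t.image for t in synth_tiles]
    masks = [t.mask.astype(int) for t in synth_tiles]
    model, _ = train_segmentation(
        tiles, masks,
        TrainConfig(epochs=60, seed=1, lr_end=1e-4),
        SegNetConfig(levels=2, channels=(8, 16), seed=1),
    )
    dices = []
    for img, mask in zip(tiles, masks):
        pred = predict_probmap(model, img).mitosis_prob() >= 0.5
        dices.append(dice(pred, mask.astype(bool)))
    assert np.mean(dices) > 0.7

    # checkpoint round trip preserves predictions exactly
    save_model(model, tmp_path / "seg.npz")
    reloaded = load_model(tmp_path / "seg.npz")
    x = tiles[0]
    assert np.array_equal(predict_probmap(model, x).probs,
                          predict_probmap(reloaded, x).probs)
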