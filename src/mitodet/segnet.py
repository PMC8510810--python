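"""U-shaped wavelet segmentation network for mitosis masks.

The encoder alternates 4-layer fully-convolutional blocks (3x3 conv +
batch norm + ReLU, no pooling) with discrete-wavelet-transform
downsampling; the decoder mirrors it with inverse-wavelet upsampling and
channel-wise skip concatenation, ending in a 1x1 projection to K class
channels.  Because the DWT is orthonormal, its adjoint equals its
inverse, so the wavelet "pooling" layers are lossless and need no
learned parameters.

The training objective is pixelwise softmax cross entropy: the negative
log-probability of each pixel's true class, summed over pixels (the
mean-per-pixel form drives the optimizer so the learning rate is
independent of tile size).  The learning rate decays log-linearly from
``lr_start`` to ``lr_end`` over the configured epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from mitodet import _nn
from mitodet._nn import Adam, BatchNorm2d, Conv2d, ReLU, Sequential

__all__ = [
    "SegNetConfig", "TrainConfig", "ProbabilityMap", "PixelLabelMap",
    "SegNet", "build_segnet", "softmax_pixelwise", "pixelwise_cross_entropy",
    "train_segmentation", "predict_probmap", "save_model", "load_model",
]


@dataclass
class SegNetConfig:
    """Architecture of the segmentation network.

    Parameters
    ----------
    levels
        Number of DWT downsampling stages (and matching IWT stages).
    block_depth
        Conv layers per CNN block; 4 by design.  Other values work but
        emit a warning since the block is defined as a 4-layer FCN.
    channels
        Feature width produced by each encoder block, one per level.
    kernel
        Spatial kernel size of the block convolutions (3 by design).
    classes
        Output class count K; class 0 is background, class 1 mitosis.
    wavelet_name
        Orthogonal wavelet used for the DWT/IWT sampling operators.
    in_channels
        Image channels (3 for RGB tiles).
    seed
        Seed for parameter initialisation.
    """

    levels: int = 3
    block_depth: int = 4
    channels: tuple[int, ...] = (32, 64, 128)
    kernel: int = 3
    classes: int = 2
    wavelet_name: str = "haar"
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.classes < 2:
            raise ValueError("classes must be >= 2")
        if len(self.channels) != self.levels:
            raise ValueError(
                f"channels must list one width per level: got {len(self.channels)} "
                f"for levels={self.levels}"
            )
        if self.block_depth != 4:
            warnings.warn(
                f"block_depth={self.block_depth}: the CNN block is defined as a "
                "4-layer FCN", stacklevel=2,
            )
        if self.wavelet_name != "haar" and not pywt.Wavelet(self.wavelet_name).orthogonal:
            raise ValueError(
                f"wavelet {self.wavelet_name!r} is not orthogonal; the network "
                "relies on adjoint == inverse for the wavelet layers"
            )


@dataclass
class TrainConfig:
    """Optimisation settings: Adam, batch 8, lr 1e-3 -> 1e-6, 100 epochs."""

    epochs: int = 100
    batch_size: int = 8
    lr_start: float = 1e-3
    lr_end: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.lr_start >= self.lr_end > 0):
            raise ValueError("require lr_start >= lr_end > 0")


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities p_k(x), shape (H, W, K).

    ``activations`` optionally keeps the pre-softmax a_k(x) of the same
    shape.  Probabilities are non-negative and sum to 1 over K at every
    pixel.
    """

    probs: np.ndarray
    activations: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if p.ndim != 3:
            raise ValueError(f"probs must be (H, W, K), got shape {p.shape}")
        if np.any(p < -1e-9):
            raise ValueError("probabilities must be non-negative")
        sums = p.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[-1]

    def mitosis_prob(self) -> np.ndarray:
        """Foreground (class 1) probability plane, shape (H, W)."""
        return self.probs[..., 1]


@dataclass
class PixelLabelMap:
    """Integer class index per pixel, shape (H, W), values in [0, K)."""

    labels: np.ndarray
    n_classes: int = 2

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {lab.shape}")
        if lab.size and (lab.min() < 0 or lab.max() >= self.n_classes):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes}); "
                f"found range [{lab.min()}, {lab.max()}]"
            )


def _block(in_ch: int, out_ch: int, depth: int, kernel: int,
           rng: np.random.Generator) -> Sequential:
    layers: list[_nn.Layer] = []
    ch = in_ch
    for _ in range(depth):
        layers += [Conv2d(ch, out_ch, kernel, rng), BatchNorm2d(out_ch), ReLU()]
        ch = out_ch
    return Sequential(layers)


def _dwt_nchw(x: np.ndarray, wavelet: str) -> np.ndarray:
    """DWT on (N, C, H, W): subbands concatenated as [LL, LH, HL, HH] blocks."""
    if wavelet == "haar":
        a = x[:, :, 0::2, 0::2]
        b = x[:, :, 0::2, 1::2]
        c = x[:, :, 1::2, 0::2]
        d = x[:, :, 1::2, 1::2]
        return np.concatenate(
            [(a + b + c + d) / 2, (a + b - c - d) / 2,
             (a - b + c - d) / 2, (a - b - c + d) / 2], axis=1,
        )
    ll, (lh, hl, hh) = pywt.dwt2(x, wavelet, mode="periodization", axes=(2, 3))
    return np.concatenate([ll, lh, hl, hh], axis=1)


def _iwt_nchw(x: np.ndarray, wavelet: str) -> np.ndarray:
    """Inverse of :func:`_dwt_nchw`; channel count must be divisible by 4."""
    c4 = x.shape[1]
    if c4 % 4:
        raise ValueError(f"channel count {c4} not divisible by 4")
    ll, lh, hl, hh = np.split(x, 4, axis=1)
    if wavelet == "haar":
        h, w = ll.shape[2], ll.shape[3]
        out = np.empty((x.shape[0], c4 // 4, 2 * h, 2 * w))
        out[:, :, 0::2, 0::2] = (ll + lh + hl + hh) / 2
        out[:, :, 0::2, 1::2] = (ll + lh - hl - hh) / 2
        out[:, :, 1::2, 0::2] = (ll - lh + hl - hh) / 2
        out[:, :, 1::2, 1::2] = (ll - lh - hl + hh) / 2
        return out
    return pywt.idwt2((ll, (lh, hl, hh)), wavelet, mode="periodization", axes=(2, 3))


class SegNet:
    """The wavelet U-shaped network, built by :func:`build_segnet`."""

    def __init__(self, config: SegNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = list(config.channels)
        L = config.levels
        self.enc_blocks = []
        in_ch = config.in_channels
        for i in range(L):
            self.enc_blocks.append(_block(in_ch, c[i], config.block_depth, config.kernel, rng))
            in_ch = 4 * c[i]
        self.bottleneck = _block(4 * c[-1], 4 * c[-1], config.block_depth, config.kernel, rng)
        # decoder block at level i consumes concat(IWT output, skip) = 2*c[i]
        # and produces 4*c[i-1] so the next IWT lands on c[i-1] channels
        self.dec_blocks = []
        for i in range(L - 1, -1, -1):
            out_ch = 4 * c[i - 1] if i > 0 else c[0]
            self.dec_blocks.append(_block(2 * c[i], out_ch, config.block_depth, config.kernel, rng))
        self.final = Conv2d(c[0], config.classes, 1, rng)
        self._skip_channels = c

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        return [*self.enc_blocks, self.bottleneck, *self.dec_blocks, self.final]

    def params(self) -> list[_nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    def num_params(self) -> int:
        """Count of trainable scalars (conv weights/biases, BN gamma/beta)."""
        return sum(p.value.size for p in self.params())

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for m in self._modules():
            layers = m.layers if isinstance(m, Sequential) else [m]
            for layer in layers:
                if isinstance(layer, BatchNorm2d):
                    arrays += [layer.running_mean, layer.running_var]
        return arrays

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, H, W) image batch -> (N, K, H, W) logits."""
        wname = self.config.wavelet_name
        L = self.config.levels
        skips = []
        for i in range(L):
            x = self.enc_blocks[i].forward(x, train)
            skips.append(x)
            x = _dwt_nchw(x, wname)
        x = self.bottleneck.forward(x, train)
        for j, i in enumerate(range(L - 1, -1, -1)):
            x = _iwt_nchw(x, wname)
            x = np.concatenate([x, skips[i]], axis=1)
            x = self.dec_blocks[j].forward(x, train)
        self._n_levels = L
        return self.final.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        wname = self.config.wavelet_name
        L = self.config.levels
        c = self._skip_channels
        grad = self.final.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        # decoder stage j was applied at level i = L-1-j; undo in reverse order
        for j in range(L - 1, -1, -1):
            i = L - 1 - j
            g = self.dec_blocks[j].backward(grad)
            skip_grads[i] = g[:, c[i]:]
            grad = _dwt_nchw(g[:, :c[i]], wname)  # adjoint of IWT
        grad = self.bottleneck.backward(grad)
        for i in range(L - 1, -1, -1):
            grad = _iwt_nchw(grad, wname)  # adjoint of DWT
            grad = grad + skip_grads[i]
            grad = self.enc_blocks[i].backward(grad)


def build_segnet(config: SegNetConfig) -> SegNet:
    """Instantiate the network with seeded, deterministic initial weights."""
    return SegNet(config)


def softmax_pixelwise(activations: np.ndarray) -> ProbabilityMap:
    """Per-pixel softmax p_k(x) = exp(a_k(x)) / sum_k' exp(a_k'(x)).

    ``activations`` has shape (H, W, K).  The computation subtracts the
    per-pixel max first, so it is invariant to a constant shift of the
    activations and never overflows.
    """
    a = np.asarray(activations, dtype=np.float64)
    if a.ndim != 3:
        raise ValueError(f"activations must be (H, W, K), got shape {a.shape}")
    if np.isnan(a).any():
        raise ValueError("activations contain NaN")
    return ProbabilityMap(probs=_nn.softmax(a, axis=-1), activations=a)


def pixelwise_cross_entropy(probmap: ProbabilityMap | np.ndarray,
                            labels: PixelLabelMap | np.ndarray) -> float:
    """Total negative log-likelihood  E = -sum_x log p_{l(x)}(x).

    Zero iff the true class has probability 1 at every pixel; grows as
    predictions disagree with the labels.  (The sum-of-logs form without
    the minus sign would be maximised, not minimised, at the optimum.)
    """
    p = probmap.probs if isinstance(probmap, ProbabilityMap) else np.asarray(probmap)
    lab = labels.labels if isinstance(labels, PixelLabelMap) else np.asarray(labels)
    if p.shape[:2] != lab.shape:
        raise ValueError(f"shape mismatch: probs {p.shape[:2]} vs labels {lab.shape}")
    k = p.shape[-1]
    if lab.size and (lab.min() < 0 or lab.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    picked = np.take_along_axis(p, lab[..., None].astype(np.intp), axis=-1)[..., 0]
    return float(-np.log(np.clip(picked, 1e-300, None)).sum())


def _pad_to_multiple(x: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad spatial axes (last two) of an NCHW array to a multiple."""
    h, w = x.shape[-2], x.shape[-1]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
        x = np.pad(x, pad, mode="reflect")
    return x, (h, w)


def _to_nchw(tile: np.ndarray) -> np.ndarray:
    img = np.asarray(tile)
    if img.ndim == 2:
        img = img[..., None]
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    return img.transpose(2, 0, 1).astype(np.float64)


def train_segmentation(
    tiles: list[np.ndarray],
    masks: list[np.ndarray],
    cfg: TrainConfig,
    net_cfg: SegNetConfig,
) -> tuple[SegNet, list[float]]:
    """Train the network on (tile, mask) pairs; returns model + loss history.

    Tiles are (H, W, 3) RGB (uint8 or float in [0, 1]); masks are (H, W)
    integer class maps.  The loss history holds the mean per-pixel cross
    entropy of each epoch.  Fully deterministic given the two seeds.
    """
    if len(tiles) == 0:
        raise ValueError("empty dataset: need at least one (tile, mask) pair")
    if len(tiles) != len(masks):
        raise ValueError(f"got {len(tiles)} tiles but {len(masks)} masks")
    for t, m in zip(tiles, masks):
        if t.shape[:2] != m.shape:
            raise ValueError(f"tile shape {t.shape[:2]} != mask shape {m.shape}")

    mult = 2 ** net_cfg.levels
    x = np.stack([_pad_to_multiple(_to_nchw(t), mult)[0] for t in tiles])
    y = np.stack([
        _pad_to_multiple(np.asarray(m, dtype=np.intp)[None], mult)[0][0] for m in masks
    ])
    if y.size and (y.min() < 0 or y.max() >= net_cfg.classes):
        raise ValueError(f"mask values must lie in [0, {net_cfg.classes})")

    model = build_segnet(net_cfg)
    opt = Adam(model.params())
    rng = np.random.default_rng(cfg.seed)
    n = len(tiles)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        if cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
        else:
            frac = 0.0
        lr = cfg.lr_start * (cfg.lr_end / cfg.lr_start) ** frac
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, grad = _nn.softmax_cross_entropy(logits, y[idx], axis=1)
            opt.zero_grad()
            model.backward(grad)
            opt.step(lr)
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return model, history


def predict_probmap(model: SegNet, tile: np.ndarray) -> ProbabilityMap:
    """Whole-tile prediction: (H, W, 3) image -> (H, W, K) probabilities.

    Odd or non-multiple sizes are reflect-padded to the next multiple of
    2**levels internally and cropped back, so the output spatial shape
    always equals the input's.
    """
    img = getattr(tile, "image", tile)
    img = np.asarray(img)
    nchw = _to_nchw(img)
    if nchw.shape[0] != model.config.in_channels:
        raise ValueError(
            f"tile has {nchw.shape[0]} channels; model expects {model.config.in_channels}"
        )
    mult = 2 ** model.config.levels
    padded, (h, w) = _pad_to_multiple(nchw, mult)
    logits = model.forward(padded[None], train=False)[0]
    logits = logits[:, :h, :w].transpose(1, 2, 0)
    return softmax_pixelwise(logits)


def save_model(model: SegNet, path) -> None:
    """Serialise weights, BN running stats and architecture to an .npz."""
    import json

    cfg = model.config
    meta = json.dumps({
        "levels": cfg.levels, "block_depth": cfg.block_depth,
        "channels": list(cfg.channels), "kernel": cfg.kernel,
        "classes": cfg.classes, "wavelet_name": cfg.wavelet_name,
        "in_channels": cfg.in_channels, "seed": cfg.seed,
    })
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_model(path) -> SegNet:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        meta["channels"] = tuple(meta["channels"])
        model = SegNet(SegNetConfig(**meta))
        for i, target in enumerate(model.state_arrays()):
            target[...] = data[f"arr_{i}"]
    return model
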