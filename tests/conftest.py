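"""Shared fixtures: small seeded synthetic tiles generated at test time."""

from dataclasses import replace

import numpy as np
import pytest

from mitodet.synthdata import SynthConfig, generate_tile, _child_seed


@pytest.fixture(scope="session")
def synth_tiles():
    """16 seeded 64x64 tiles with 2-4 well-separated mitoses each."""
    cfg = SynthConfig(n_mitoses_range=(2, 4), seed=1)
    return [generate_tile(replace(cfg, seed=_child_seed(1, i))) for i in range(16)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred, truth).sum()
    denom = pred.sum() + truth.sum()
    return 2.0 * inter / denom if denom else 1.0
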