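"""Single-level 2-D discrete wavelet transform and its inverse.

These are the down/upsampling operators of the segmentation network:
``dwt2`` splits a plane into one low-frequency (LL) and three
high-frequency (LH, HL, HH) half-resolution subbands, and ``iwt2``
reconstructs the plane exactly.  With the default orthonormal Haar
filter the transform conserves energy and its adjoint equals its
inverse, which is what makes it usable as a lossless pooling layer.

Subband naming follows PyWavelets: ``lh`` is the horizontal-detail band
(cH), ``hl`` the vertical-detail band (cV) and ``hh`` the diagonal band
(cD).  All subbands carry the orthonormal "periodization" scaling, so
one 2-D level contributes a factor 1/2 per coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["SubbandSet", "dwt2", "iwt2"]


@dataclass
class SubbandSet:
    """The four half-resolution coefficient planes of one DWT level.

    Each plane has shape (H/2, W/2) or (H/2, W/2, C) for an input of
    shape (H, W[, C]).  All four planes share one shape.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    wavelet_name: str = "haar"

    def __post_init__(self) -> None:
        shapes = {p.shape for p in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(
                f"subband shapes differ: ll {self.ll.shape}, lh {self.lh.shape}, "
                f"hl {self.hl.shape}, hh {self.hh.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape

    def stack(self) -> np.ndarray:
        """Stack the four planes along a leading axis (4, H/2, W/2[, C])."""
        return np.stack([self.ll, self.lh, self.hl, self.hh], axis=0)


def _check_even(plane: np.ndarray) -> None:
    if plane.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D array, got ndim={plane.ndim}")
    for axis in (0, 1):
        if plane.shape[axis] % 2 != 0:
            raise ValueError(
                f"spatial axis {axis} has odd length {plane.shape[axis]}; "
                "pad to an even size before transforming"
            )


def dwt2(plane: np.ndarray, wavelet: str = "haar") -> SubbandSet:
    """Single-level 2-D DWT of a (H, W[, C]) plane into four subbands.

    Channels (axis 2) are transformed independently.  Spatial dimensions
    must be even; callers pad upstream rather than letting the transform
    silently extend the signal.

    Parameters
    ----------
    plane
        Real array of shape (H, W) or (H, W, C) with H, W even.
    wavelet
        PyWavelets filter name.  The default Haar uses a direct
        vectorised path; any other orthogonal wavelet goes through
        PyWavelets with periodization boundary handling, which keeps
        the transform orthonormal.
    """
    plane = np.asarray(plane, dtype=np.float64)
    _check_even(plane)
    if wavelet == "haar":
        a = plane[0::2, 0::2]
        b = plane[0::2, 1::2]
        c = plane[1::2, 0::2]
        d = plane[1::2, 1::2]
        ll = (a + b + c + d) / 2.0
        lh = (a + b - c - d) / 2.0
        hl = (a - b + c - d) / 2.0
        hh = (a - b - c + d) / 2.0
    else:
        ll, (lh, hl, hh) = pywt.dwt2(plane, wavelet, mode="periodization", axes=(0, 1))
    return SubbandSet(ll=ll, lh=lh, hl=hl, hh=hh, wavelet_name=wavelet)


def iwt2(subbands: SubbandSet) -> np.ndarray:
    """Inverse of :func:`dwt2`: reconstruct the full-resolution plane.

    Output spatial dimensions are exactly double the subband dimensions;
    for an orthonormal filter the round trip is exact to floating-point
    precision.
    """
    ll, lh, hl, hh = subbands.ll, subbands.lh, subbands.hl, subbands.hh
    if subbands.wavelet_name == "haar":
        h, w = ll.shape[0], ll.shape[1]
        out = np.empty((2 * h, 2 * w) + ll.shape[2:], dtype=np.float64)
        out[0::2, 0::2] = (ll + lh + hl + hh) / 2.0
        out[0::2, 1::2] = (ll + lh - hl - hh) / 2.0
        out[1::2, 0::2] = (ll - lh + hl - hh) / 2.0
        out[1::2, 1::2] = (ll - lh - hl + hh) / 2.0
        return out
    return pywt.idwt2(
        (ll, (lh, hl, hh)), subbands.wavelet_name, mode="periodization", axes=(0, 1)
    )
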