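"""Single-level undecimated 3D separable wavelet decomposition (coif1).

Low (L) and high (H) pass analysis filters are applied along each image
axis in turn, giving the eight subbands LLL ... HHH on the same grid as the
input (no decimation), so the lesion mask applies to every subband directly.
Boundaries use half-sample symmetric extension.  Filters are the coif1
analysis pair normalized to unit DC gain of the low-pass, so LLL preserves
the local mean and every subband with an H factor annihilates constants.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import correlate1d

from ..image import ImageVolume
from .registry import WAVELET_TAGS

_WAVELET = "coif1"


def analysis_filters(wavelet: str = _WAVELET) -> tuple[np.ndarray, np.ndarray]:
    """(low, high) analysis filters, low-pass normalized to sum to 1."""
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    scale = lo.sum()  # sqrt(2) for orthogonal wavelets
    return lo / scale, hi / scale


def _filter_axis(data: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    # correlation with the analysis filter, half-sample symmetric boundary
    return correlate1d(data, taps, axis=axis, mode="reflect")


def wavelet_decompose_3d(vol: ImageVolume, wavelet: str = _WAVELET) -> dict[str, ImageVolume]:
    """Return the 8 subbands keyed LLL..HHH, each on the input grid."""
    lo, hi = analysis_filters(wavelet)
    if min(vol.shape) < len(lo):
        raise ValueError(
            f"volume shape {vol.shape} smaller than the {wavelet} filter support ({len(lo)})"
        )
    data = np.asarray(vol.data, dtype=np.float64)
    out: dict[str, ImageVolume] = {}
    for tag in WAVELET_TAGS:
        cur = data
        for axis, letter in enumerate(tag):
            taps = lo if letter == "L" else hi
            cur = _filter_axis(cur, taps, axis)
        out[tag] = vol.with_data(cur)
    return out
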