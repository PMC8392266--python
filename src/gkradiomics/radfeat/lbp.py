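"""Rotation-invariant uniform local binary patterns, pooled across slices.

LBP codes are computed slice-by-slice along the third axis with 8
neighbours at radius 1 using the riu2 mapping (scikit-image ``uniform``
method), which has exactly 10 distinct codes: 0..8 for uniform patterns
(number of set bits) and 9 for non-uniform patterns.  Codes at in-mask
voxels are pooled over all slices and reported as the normalized 10-bin
histogram.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.feature import local_binary_pattern

from .registry import LBP_FEATURES

N_NEIGHBOURS = 8
RADIUS = 1
N_CODES = N_NEIGHBOURS + 2  # riu2: 0..P uniform + one non-uniform bin


def lbp_features(data: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Normalized riu2 LBP code histogram over in-mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    data = np.asarray(data, dtype=np.float64)
    counts = np.zeros(N_CODES, dtype=np.float64)
    for k in range(data.shape[2]):
        mslice = mask[:, :, k]
        if not mslice.any():
            continue
        # mirror-pad so in-mask voxels on the slice border see valid
        # neighbours instead of scikit-image's implicit zero boundary
        # (mirroring, unlike edge replication, avoids samples that tie
        # exactly with the center pixel)
        padded = np.pad(data[:, :, k], RADIUS, mode="reflect")
        with warnings.catch_warnings():
            # float input is intentional: Z-scored / wavelet-filtered images
            warnings.simplefilter("ignore", UserWarning)
            codes = local_binary_pattern(padded, N_NEIGHBOURS, RADIUS, method="uniform")
        codes = codes[RADIUS:-RADIUS, RADIUS:-RADIUS]
        binned = np.bincount(codes[mslice].astype(np.int64), minlength=N_CODES)
        counts += binned[:N_CODES]
    hist = counts / counts.sum()
    return {name: float(hist[i]) for i, name in enumerate(LBP_FEATURES)}
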