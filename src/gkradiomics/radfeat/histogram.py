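"""First-order (histogram) features of in-mask intensities.

Fourteen statistics are computed directly on the raw in-mask values;
entropy and uniformity are computed on the equal-width discretized
distribution (same gray-level count as the texture features) so they are
invariant to affine intensity rescaling.  Skewness and kurtosis of a
constant ROI are reported as 0 (the moment ratios are undefined there).
Kurtosis is the non-excess (Pearson) definition: 3 for a Gaussian.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .texture import discretize_roi


def histogram_features(data: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(data, dtype=np.float64)[mask]

    levels = discretize_roi(data, mask, n_levels).levels[mask]
    p = np.bincount(levels, minlength=n_levels + 1)[1:].astype(np.float64)
    p /= p.sum()
    pz = p[p > 0]
    entropy = float(-(pz * np.log2(pz)).sum())
    uniformity = float((p**2).sum())

    sd = float(x.std())
    # near-constant ROIs (e.g. a low-pass band of a constant lesion) hit
    # catastrophic cancellation in the moment ratios; report 0 there
    if sd > 1e-10 * max(1.0, abs(float(x.mean()))):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skewness = float(stats.skew(x))
            kurtosis = float(stats.kurtosis(x, fisher=False))
        if not np.isfinite(skewness):
            skewness = 0.0
        if not np.isfinite(kurtosis):
            kurtosis = 0.0
    else:
        skewness = 0.0
        kurtosis = 0.0
    q10, q25, q50, q75, q90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "mean": float(x.mean()),
        "median": float(q50),
        "range": float(x.max() - x.min()),
        "variance": float(x.var()),
        "std": sd,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "uniformity": uniformity,
        "p10": float(q10),
        "p90": float(q90),
        "iqr": float(q75 - q25),
        "mad": float(np.abs(x - x.mean()).mean()),
    }
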