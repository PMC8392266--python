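"""Assembly of the full 1763-entry feature vector for one lesion.

Per contrast, the original image and its 8 undecimated coif1 subbands each
yield 16 histogram + 26 GLCM + 13 GLRLM + 10 LBP features inside the lesion
mask; 8 geometry features come from the mask alone.  For speed, volumes are
cropped to the mask bounding box plus a margin covering the wavelet filter
support and LBP radius before filtering, which leaves in-mask feature
values unchanged whenever the lesion is not flush against the volume edge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..image import CONTRASTS, ImageVolume
from .geometry import geometry_features
from .histogram import histogram_features
from .lbp import lbp_features
from .registry import registry_names
from .texture import discretize_roi, glcm_features, glrlm_features
from .wavelet import wavelet_decompose_3d

# margin ≥ coif1 support (6 taps) and LBP radius
_CROP_MARGIN = 6


def crop_to_mask(data: np.ndarray, mask: np.ndarray, margin: int = _CROP_MARGIN):
    """Crop volume and mask to the mask bounding box plus a margin."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return data[sl], mask[sl]


def image_set_features(data: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """16 histogram + 49 texture features of one image set inside the mask."""
    feats: dict[str, float] = {}
    for name, v in histogram_features(data, mask, n_levels).items():
        feats[f"histogram.{name}"] = v
    roi = discretize_roi(data, mask, n_levels)
    for name, v in glcm_features(roi).items():
        feats[f"glcm.{name}"] = v
    for name, v in glrlm_features(roi).items():
        feats[f"glrlm.{name}"] = v
    for name, v in lbp_features(data, mask).items():
        feats[f"lbp.{name}"] = v
    return feats


def extract_all(
    t1w: ImageVolume,
    t1c: ImageVolume,
    t2w: ImageVolume,
    mask: np.ndarray,
    n_levels: int = 32,
) -> pd.Series:
    """The named 1763-entry radiomic profile of one lesion.

    All three contrasts must share the mask grid and spacing; the returned
    Series is indexed by the fixed registry order and is finite everywhere.
    """
    vols = {"T1w": t1w, "T1c": t1c, "T2w": t2w}
    mask = np.asarray(mask, dtype=bool)
    shapes = {c: v.shape for c, v in vols.items()}
    if len({*shapes.values(), mask.shape}) != 1:
        raise ValueError(f"grid mismatch between contrasts/mask: {shapes}, mask {mask.shape}")
    spacings = {tuple(np.round(v.spacing, 9)) for v in vols.values()}
    if len(spacings) != 1:
        raise ValueError("contrasts do not share voxel spacing")
    if not mask.any():
        raise ValueError("empty mask")

    values: dict[str, float] = {}
    for contrast in CONTRASTS:
        data, cmask = crop_to_mask(np.asarray(vols[contrast].data, dtype=np.float64), mask)
        sub = ImageVolume(data=data, spacing=vols[contrast].spacing, contrast=contrast)
        image_sets = {"none": data}
        for tag, band in wavelet_decompose_3d(sub).items():
            image_sets[tag] = band.data
        for tag, arr in image_sets.items():
            for name, v in image_set_features(arr, cmask, n_levels).items():
                values[f"{contrast}.{tag}.{name}"] = v
    for name, v in geometry_features(mask, t1c.spacing).items():
        values[f"shape.none.geometry.{name}"] = v

    names = registry_names()
    out = pd.Series([values[n] for n in names], index=names, dtype=np.float64)
    if not np.all(np.isfinite(out.to_numpy())):
        bad = out.index[~np.isfinite(out.to_numpy())].tolist()
        raise AssertionError(f"non-finite features: {bad[:5]}")
    return out


def extract_cohort_features(cohort, n_levels: int = 32) -> pd.DataFrame:
    """Feature table for every lesion of a synthetic cohort.

    Rows are indexed (patient_id, lesion_id); columns follow the registry.
    Volumes are Z-scored per whole image before extraction, matching the
    preprocessing contract.
    """
    from ..imgprep import zscore_normalize

    rows = []
    index = []
    for patient in cohort.patients:
        vols = {c: zscore_normalize(v) for c, v in patient.volumes.items()}
        for lesion in patient.lesions:
            fv = extract_all(vols["T1w"], vols["T1c"], vols["T2w"], lesion.mask, n_levels)
            rows.append(fv)
            index.append((patient.patient_id, lesion.lesion_id))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["patient_id", "lesion_id"])
    )
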