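"""The fixed 1763-entry radiomic feature registry.

Per contrast (T1w, T1c, T2w) the original image and 8 wavelet subbands each
yield 16 histogram + 49 texture (26 GLCM + 13 GLRLM + 10 LBP) features:
9 x 65 = 585 per contrast.  Eight geometry features are mask-only, giving
585 x 3 + 8 = 1763 in total.  Entry names follow
``contrast.filter.family.feature`` (geometry uses ``shape.none.geometry.*``).
"""

from __future__ import annotations

from ..image import CONTRASTS

WAVELET_TAGS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
IMAGE_SETS = ("none",) + WAVELET_TAGS

HISTOGRAM_FEATURES = (
    "energy",
    "entropy",
    "minimum",
    "maximum",
    "mean",
    "median",
    "range",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "uniformity",
    "p10",
    "p90",
    "iqr",
    "mad",
)

GLCM_FEATURES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
    "joint_average",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
    "mcc",
)

GLRLM_FEATURES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
    "glv",
    "rlv",
)

LBP_FEATURES = tuple(f"lbp_{i}" for i in range(10))

GEOMETRY_FEATURES = (
    "volume_mm3",
    "surface_area_mm2",
    "surface_to_volume",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "max_diameter_mm",
)

assert len(GLCM_FEATURES) + len(GLRLM_FEATURES) + len(LBP_FEATURES) == 49
assert len(HISTOGRAM_FEATURES) == 16


def build_feature_registry() -> list[tuple[str, str, str, str]]:
    """Ordered (contrast, filter_tag, family, feature) tuples; length 1763."""
    entries: list[tuple[str, str, str, str]] = []
    for contrast in CONTRASTS:
        for tag in IMAGE_SETS:
            for name in HISTOGRAM_FEATURES:
                entries.append((contrast, tag, "histogram", name))
            for name in GLCM_FEATURES:
                entries.append((contrast, tag, "glcm", name))
            for name in GLRLM_FEATURES:
                entries.append((contrast, tag, "glrlm", name))
            for name in LBP_FEATURES:
                entries.append((contrast, tag, "lbp", name))
    for name in GEOMETRY_FEATURES:
        entries.append(("shape", "none", "geometry", name))
    return entries


def registry_names() -> list[str]:
    """Flat ``contrast.filter.family.feature`` column names in fixed order."""
    return [".".join(e) for e in build_feature_registry()]
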