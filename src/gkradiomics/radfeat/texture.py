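"""Gray-level discretization, GLCM and GLRLM texture features.

Both matrix families are computed in 3D over the 13 unique voxel
displacement directions at distance 1; per-direction features are averaged
to approximate rotational invariance.  Gray levels come from equal-width
binning of in-mask intensities (default 32 levels, set at extraction time).

Degenerate conventions (single gray level, zero marginal variance) replace
undefined values with 0 (correlation, IMC1, MCC) so feature vectors stay
finite on constant lesions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .registry import GLCM_FEATURES, GLRLM_FEATURES

# 13 unique direction offsets of the 26-connected 3D neighbourhood
# (one representative per +/- pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..n_levels) for in-mask voxels on a 3D grid.

    ``levels`` holds 0 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize_roi(data: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> DiscretizedROI:
    """Equal-width binning of in-mask intensities into ``n_levels`` levels.

    Bins cover [min, max] of in-mask values; the top bin is right-closed.
    A constant ROI (or ``n_levels`` = 1) maps every voxel to level 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    vals = np.asarray(data, dtype=np.float64)[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo or n_levels == 1:
        levels[mask] = 1
    else:
        width = (hi - lo) / n_levels
        lv = np.floor((vals - lo) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
        levels[mask] = lv
    return DiscretizedROI(levels=levels, mask=mask, n_levels=int(n_levels))


# ---------------------------------------------------------------------- #
# GLCM
# ---------------------------------------------------------------------- #
def glcm_matrix(roi: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one displacement.

    Returns the all-zero matrix when the direction has no valid in-mask pair.
    """
    ng = roi.n_levels
    lv = roi.levels
    d = direction
    sl_a = tuple(slice(max(0, -o), lv.shape[ax] - max(0, o)) for ax, o in enumerate(d))
    sl_b = tuple(slice(max(0, o), lv.shape[ax] - max(0, -o)) for ax, o in enumerate(d))
    a, b = lv[sl_a], lv[sl_b]
    valid = (a > 0) & (b > 0)
    counts = np.zeros((ng, ng), dtype=np.float64)
    if valid.any():
        idx = (a[valid].astype(np.int64) - 1) * ng + (b[valid].astype(np.int64) - 1)
        flat = np.bincount(idx, minlength=ng * ng).astype(np.float64)
        counts = flat.reshape(ng, ng)
        counts = counts + counts.T  # symmetric: count both orderings
        counts /= counts.sum()
    return counts


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    """The 26 registry GLCM features of one normalized co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    diff = np.abs(ii - jj)
    # p_{x+y}(k), k = 2..2Ng  and  p_{x-y}(k), k = 0..Ng-1
    sum_idx = (ii + jj - 2).astype(np.int64)
    diff_idx = diff.astype(np.int64)
    psum = np.bincount(sum_idx.ravel(), weights=p.ravel(), minlength=2 * ng - 1)
    pdiff = np.bincount(diff_idx.ravel(), weights=p.ravel(), minlength=ng)
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kdiff = np.arange(0, ng, dtype=np.float64)

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    hxy = _ent(p.ravel())
    hx = _ent(px)
    hy = _ent(py)
    pxy_outer = np.outer(px, py)
    nz = (p > 0) & (pxy_outer > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy_outer[nz])).sum())
    nz2 = pxy_outer > 0
    hxy2 = float(-(pxy_outer[nz2] * np.log2(pxy_outer[nz2])).sum())

    out: dict[str, float] = {}
    out["autocorrelation"] = float((ii * jj * p).sum())
    mu_sum = mu_x + mu_y
    out["cluster_tendency"] = float(((ii + jj - mu_sum) ** 2 * p).sum())
    out["cluster_shade"] = float(((ii + jj - mu_sum) ** 3 * p).sum())
    out["cluster_prominence"] = float(((ii + jj - mu_sum) ** 4 * p).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    denom = np.sqrt(var_x * var_y)
    out["correlation"] = (
        float(((ii * jj * p).sum() - mu_x * mu_y) / denom) if denom > 0 else 0.0
    )
    out["difference_average"] = float((kdiff * pdiff).sum())
    out["difference_entropy"] = _ent(pdiff)
    out["difference_variance"] = float(((kdiff - (kdiff * pdiff).sum()) ** 2 * pdiff).sum())
    out["dissimilarity"] = float((diff * p).sum())
    out["energy"] = float((p**2).sum())
    out["entropy"] = hxy
    out["homogeneity1"] = float((p / (1.0 + diff)).sum())
    out["homogeneity2"] = float((p / (1.0 + diff**2)).sum())
    hmax = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / hmax) if hmax > 0 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    out["idmn"] = float((p / (1.0 + diff**2 / ng**2)).sum())
    out["idn"] = float((p / (1.0 + diff / ng)).sum())
    off = diff > 0
    out["inverse_variance"] = float((p[off] / diff[off] ** 2).sum()) if off.any() else 0.0
    out["joint_average"] = mu_x
    out["max_probability"] = float(p.max())
    out["sum_average"] = float((ksum * psum).sum())
    out["sum_entropy"] = _ent(psum)
    out["sum_variance"] = float(((ksum - (ksum * psum).sum()) ** 2 * psum).sum())
    out["variance"] = float(((ii - mu_x) ** 2 * p).sum())
    out["mcc"] = _mcc(p, px, py)
    return out


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the 2nd eigenvalue of Q."""
    keep = px > 0
    if keep.sum() < 2:
        return 0.0
    ps = p[np.ix_(keep, keep)]
    pxs = px[keep]
    pys = py[keep]
    # Q[i,j] = sum_k p[i,k] p[j,k] / (px[i] py[k])
    q = (ps / pxs[:, None]) @ (ps / pys[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    if ev.size < 2:
        return 0.0
    return float(np.sqrt(np.clip(ev[1], 0.0, 1.0)))


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """Direction-averaged GLCM features (13 unique 3D directions)."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    per_dir = []
    for d in DIRECTIONS_3D:
        p = glcm_matrix(roi, d)
        if p.sum() > 0:
            per_dir.append(glcm_features_from_matrix(p))
    if not per_dir:
        # isolated voxels with no neighbour pair in any direction
        feats = glcm_features_from_matrix(np.ones((1, 1)))
        return {k: feats.get(k, 0.0) for k in GLCM_FEATURES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------- #
# GLRLM
# ---------------------------------------------------------------------- #
@lru_cache(maxsize=256)
def _line_geometry(shape: tuple[int, int, int], direction: tuple[int, int, int]):
    """Flat voxel indices of every direction line; cached per (shape, dir)."""
    shape_a = np.asarray(shape)
    d = np.asarray(direction)
    # line starts: in-bounds voxels whose predecessor along d is out of bounds
    grid = np.indices(shape).reshape(3, -1).T
    prev = grid - d
    oob = ((prev < 0) | (prev >= shape_a)).any(axis=1)
    starts = grid[oob]
    # steps along a line are bounded by the smallest traversed axis extent
    max_run = int(min(shape[a] for a in range(3) if d[a] != 0))
    t = np.arange(max_run)
    pos = starts[:, None, :] + t[None, :, None] * d  # (n_lines, L, 3)
    valid = ((pos >= 0) & (pos < shape_a)).all(axis=2)
    pc = np.clip(pos, 0, shape_a - 1)
    flat_idx = np.ravel_multi_index((pc[..., 0], pc[..., 1], pc[..., 2]), shape)
    return flat_idx, valid, max_run


def glrlm_matrix(roi: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] for one direction.

    A run is a maximal set of collinear, equal-level, in-mask voxels along
    the direction; voxels outside the mask break runs.
    """
    lv = roi.levels
    ng = roi.n_levels
    flat_idx, valid, max_run = _line_geometry(lv.shape, tuple(direction))
    vals = np.where(valid, lv.ravel()[flat_idx], 0).astype(np.int64)

    # flatten all lines with a zero separator, then run-length encode
    x = np.concatenate([vals, np.zeros((vals.shape[0], 1), dtype=np.int64)], axis=1).ravel()
    change = np.flatnonzero(np.diff(x) != 0) + 1
    bounds = np.concatenate([[0], change, [len(x)]])
    run_vals = x[bounds[:-1]]
    run_lens = np.diff(bounds)
    keep = run_vals > 0
    rv, rl = run_vals[keep], run_lens[keep]
    counts = np.bincount((rv - 1) * max_run + (rl - 1), minlength=ng * max_run).astype(np.float64)
    return counts.reshape(ng, max_run)


def glrlm_features_from_matrix(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 13 classical run-length features of one run matrix."""
    nr = r.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_FEATURES}
    g = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    l_ = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    rg = r.sum(axis=1)
    rl = r.sum(axis=0)
    pr = r / nr
    mu_g = float((pr * g).sum())
    mu_l = float((pr * l_).sum())
    return {
        "sre": float((r / l_**2).sum() / nr),
        "lre": float((r * l_**2).sum() / nr),
        "gln": float((rg**2).sum() / nr),
        "rln": float((rl**2).sum() / nr),
        "rp": float(nr / n_voxels),
        "lgre": float((r / g**2).sum() / nr),
        "hgre": float((r * g**2).sum() / nr),
        "srlge": float((r / (g**2 * l_**2)).sum() / nr),
        "srhge": float((r * g**2 / l_**2).sum() / nr),
        "lrlge": float((r * l_**2 / g**2).sum() / nr),
        "lrhge": float((r * g**2 * l_**2).sum() / nr),
        "glv": float((pr * (g - mu_g) ** 2).sum()),
        "rlv": float((pr * (l_ - mu_l) ** 2).sum()),
    }


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """Direction-averaged GLRLM features (13 unique 3D directions)."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    per_dir = [
        glrlm_features_from_matrix(glrlm_matrix(roi, d), roi.n_voxels)
        for d in DIRECTIONS_3D
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}
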