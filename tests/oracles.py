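"""Independent brute-force oracles for feature extraction tests.

Everything here is written as plainly as possible — explicit Python loops,
pair/run enumeration, dense convolution — and deliberately shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------- #
# GLCM by ordered-pair enumeration
# ---------------------------------------------------------------------- #
def glcm_matrix_bruteforce(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by enumerating voxel pairs."""
    shape = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                a = levels[i, j, k]
                if a == 0:
                    continue
                for sign in (1, -1):
                    ii, jj, kk = (
                        i + sign * direction[0],
                        j + sign * direction[1],
                        k + sign * direction[2],
                    )
                    if 0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]:
                        b = levels[ii, jj, kk]
                        if b > 0:
                            counts[a - 1, b - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features_bruteforce(p: np.ndarray) -> dict:
    """All 26 GLCM features by direct looping over the matrix."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))

    psum = [0.0] * (2 * ng - 1)  # index k-2 for k = i+j in 2..2Ng
    pdiff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]

    def ent(q):
        return -sum(v * math.log2(v) for v in q if v > 0)

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )

    f = {}
    f["autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_s = mu_x + mu_y
    f["cluster_tendency"] = sum((i + j + 2 - mu_s) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["cluster_shade"] = sum((i + j + 2 - mu_s) ** 3 * p[i, j] for i in range(ng) for j in range(ng))
    f["cluster_prominence"] = sum((i + j + 2 - mu_s) ** 4 * p[i, j] for i in range(ng) for j in range(ng))
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    denom = math.sqrt(var_x * var_y)
    f["correlation"] = (
        (f["autocorrelation"] - mu_x * mu_y) / denom if denom > 0 else 0.0
    )
    da = sum(k * pdiff[k] for k in range(ng))
    f["difference_average"] = da
    f["difference_entropy"] = ent(pdiff)
    f["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in range(ng))
    f["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    f["energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["entropy"] = hxy
    f["homogeneity1"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["homogeneity2"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    hmax = max(hx, hy)
    f["imc1"] = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    f["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["idmn"] = sum(p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    f["idn"] = sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["joint_average"] = mu_x
    f["max_probability"] = max(p[i, j] for i in range(ng) for j in range(ng))
    sa = sum((k + 2) * psum[k] for k in range(2 * ng - 1))
    f["sum_average"] = sa
    f["sum_entropy"] = ent(psum)
    f["sum_variance"] = sum((k + 2 - sa) ** 2 * psum[k] for k in range(2 * ng - 1))
    f["variance"] = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["mcc"] = _mcc_bruteforce(p, px, py)
    return f


def _mcc_bruteforce(p, px, py):
    ng = p.shape[0]
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) < 2:
        return 0.0
    q = np.zeros((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            q[a, b] = sum(
                p[i, k] * p[j, k] / (px[i] * py[k]) for k in range(ng) if py[k] > 0
            )
    ev = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
    return math.sqrt(min(max(ev[1], 0.0), 1.0))


# ---------------------------------------------------------------------- #
# GLRLM by line walking
# ---------------------------------------------------------------------- #
def glrlm_matrix_bruteforce(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run-length matrix by walking every line voxel by voxel."""
    shape = levels.shape
    max_run = max(shape)
    counts = np.zeros((n_levels, max_run), dtype=float)
    d = direction
    starts = [
        (i, j, k)
        for i in range(shape[0])
        for j in range(shape[1])
        for k in range(shape[2])
        if not (
            0 <= i - d[0] < shape[0]
            and 0 <= j - d[1] < shape[1]
            and 0 <= k - d[2] < shape[2]
        )
    ]
    for s in starts:
        pos = list(s)
        run_val, run_len = 0, 0
        while 0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1] and 0 <= pos[2] < shape[2]:
            v = int(levels[tuple(pos)])
            if v == run_val and v > 0:
                run_len += 1
            else:
                if run_val > 0:
                    counts[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, (1 if v > 0 else 0)
            pos = [pos[a] + d[a] for a in range(3)]
        if run_val > 0:
            counts[run_val - 1, run_len - 1] += 1
    return counts


def glrlm_features_bruteforce(r: np.ndarray, n_voxels: int) -> dict:
    nr = r.sum()
    if nr == 0:
        return {k: 0.0 for k in (
            "sre lre gln rln rp lgre hgre srlge srhge lrlge lrhge glv rlv".split()
        )}
    ng, nl = r.shape
    f = {}
    f["sre"] = sum(r[g, l] / (l + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    f["lre"] = sum(r[g, l] * (l + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    f["gln"] = sum(sum(r[g, :]) ** 2 for g in range(ng)) / nr
    f["rln"] = sum(sum(r[:, l]) ** 2 for l in range(nl)) / nr
    f["rp"] = nr / n_voxels
    f["lgre"] = sum(r[g, l] / (g + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    f["hgre"] = sum(r[g, l] * (g + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    f["srlge"] = sum(r[g, l] / ((g + 1) ** 2 * (l + 1) ** 2) for g in range(ng) for l in range(nl)) / nr
    f["srhge"] = sum(r[g, l] * (g + 1) ** 2 / (l + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    f["lrlge"] = sum(r[g, l] * (l + 1) ** 2 / (g + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    f["lrhge"] = sum(r[g, l] * (g + 1) ** 2 * (l + 1) ** 2 for g in range(ng) for l in range(nl)) / nr
    mu_g = sum((g + 1) * r[g, l] / nr for g in range(ng) for l in range(nl))
    mu_l = sum((l + 1) * r[g, l] / nr for g in range(ng) for l in range(nl))
    f["glv"] = sum((g + 1 - mu_g) ** 2 * r[g, l] / nr for g in range(ng) for l in range(nl))
    f["rlv"] = sum((l + 1 - mu_l) ** 2 * r[g, l] / nr for g in range(ng) for l in range(nl))
    return f


# ---------------------------------------------------------------------- #
# LBP by per-pixel bitstring enumeration
# ---------------------------------------------------------------------- #
def lbp_code_bruteforce(img: np.ndarray, row: int, col: int, p: int = 8, r: float = 1.0) -> int:
    """riu2 code of one pixel: bilinear samples on the radius-r circle."""
    bits = []
    for k in range(p):
        theta = 2.0 * math.pi * k / p
        rr = row + r * math.sin(theta)
        cc = col + r * math.cos(theta)
        r0, c0 = int(math.floor(rr)), int(math.floor(cc))
        fr, fc = rr - r0, cc - c0
        def reflect(idx, n):
            if idx < 0:
                return -idx
            if idx > n - 1:
                return 2 * (n - 1) - idx
            return idx

        val = 0.0
        for dr, wr in ((0, 1 - fr), (1, fr)):
            for dc, wc in ((0, 1 - fc), (1, fc)):
                ri = reflect(r0 + dr, img.shape[0])
                ci = reflect(c0 + dc, img.shape[1])
                val += wr * wc * img[ri, ci]
        # tolerance against interpolation round-off, as in scikit-image
        bits.append(1 if val - img[row, col] >= -1e-13 * abs(img[row, col]) else 0)
    transitions = sum(bits[k] != bits[(k + 1) % p] for k in range(p))
    if transitions <= 2:
        return sum(bits)
    return p + 1


def lbp_histogram_bruteforce(data3d: np.ndarray, mask: np.ndarray, p: int = 8) -> np.ndarray:
    counts = np.zeros(p + 2)
    for k in range(data3d.shape[2]):
        for i in range(data3d.shape[0]):
            for j in range(data3d.shape[1]):
                if mask[i, j, k]:
                    counts[lbp_code_bruteforce(data3d[:, :, k], i, j, p)] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------- #
# histogram statistics, computed directly
# ---------------------------------------------------------------------- #
def histogram_features_bruteforce(data: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> dict:
    x = sorted(float(v) for v in np.asarray(data)[np.asarray(mask, bool)])
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    lo, hi = x[0], x[-1]
    if hi > lo:
        width = (hi - lo) / n_levels
        bins = [min(int((v - lo) / width), n_levels - 1) for v in x]
    else:
        bins = [0] * n
    probs = [bins.count(b) / n for b in range(n_levels)]
    entropy = -sum(q * math.log2(q) for q in probs if q > 0)
    uniformity = sum(q**2 for q in probs)
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / sd**4
    else:
        skew = kurt = 0.0
    return {
        "energy": sum(v**2 for v in x),
        "entropy": entropy,
        "minimum": lo,
        "maximum": hi,
        "mean": mean,
        "median": float(np.percentile(x, 50)),
        "range": hi - lo,
        "variance": var,
        "std": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "uniformity": uniformity,
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "mad": sum(abs(v - mean) for v in x) / n,
    }


# ---------------------------------------------------------------------- #
# geometry by face counting and pairwise distances
# ---------------------------------------------------------------------- #
def geometry_features_bruteforce(mask: np.ndarray, spacing) -> dict:
    mask = np.asarray(mask, bool)
    sx, sy, sz = (float(s) for s in spacing)
    n = int(mask.sum())
    volume = n * sx * sy * sz
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    area = 0.0
    surface_voxels = set()
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            for k in range(mask.shape[2]):
                if not mask[i, j, k]:
                    continue
                for axis, (di, dj, dk) in enumerate(
                    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
                ):
                    ni, nj, nk = i + di, j + dj, k + dk
                    outside = not (
                        0 <= ni < mask.shape[0]
                        and 0 <= nj < mask.shape[1]
                        and 0 <= nk < mask.shape[2]
                    ) or not mask[ni, nj, nk]
                    if outside:
                        area += face_area[axis // 2]
                        surface_voxels.add((i, j, k))
    pts = [(i * sx, j * sy, k * sz) for i, j, k in surface_voxels]
    max_diam = 0.0
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            d = math.dist(pts[a], pts[b])
            max_diam = max(max_diam, d)
    r_eq = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * math.pi * r_eq**2
    return {
        "volume_mm3": volume,
        "surface_area_mm2": area,
        "surface_to_volume": area / volume,
        "sphericity": sphere_area / area,
        "compactness1": volume / (math.sqrt(math.pi) * area**1.5),
        "compactness2": 36.0 * math.pi * volume**2 / area**3,
        "spherical_disproportion": area / sphere_area,
        "max_diameter_mm": max_diam,
    }


# ---------------------------------------------------------------------- #
# separable filtering by explicit padded correlation
# ---------------------------------------------------------------------- #
def correlate_axis_bruteforce(data: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """1D correlation along an axis with half-sample symmetric extension.

    Matches scipy's ``correlate1d(..., mode="reflect")`` placement: the tap
    at index ``len(taps)//2`` sits on the output voxel.
    """
    m = len(taps)
    center = m // 2
    pad = [(0, 0)] * 3
    pad[axis] = (center, m - 1 - center)
    padded = np.pad(data, pad, mode="symmetric")
    out = np.zeros_like(data, dtype=float)
    for idx in np.ndindex(data.shape):
        acc = 0.0
        for t in range(m):
            src = list(idx)
            src[axis] = idx[axis] + t
            acc += taps[t] * padded[tuple(src)]
        out[idx] = acc
    return out


def wavelet_band_bruteforce(data: np.ndarray, lo: np.ndarray, hi: np.ndarray, tag: str) -> np.ndarray:
    out = data.astype(float)
    for axis, letter in enumerate(tag):
        out = correlate_axis_bruteforce(out, lo if letter == "L" else hi, axis)
    return out


def trilinear_sample_bruteforce(data: np.ndarray, spacing, point_mm) -> float:
    """Trilinear interpolation of a grid at a physical point (origin 0)."""
    coords = [p / s for p, s in zip(point_mm, spacing)]
    base = [int(math.floor(c)) for c in coords]
    frac = [c - b for c, b in zip(coords, base)]
    val = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (frac[0] if di else 1 - frac[0])
                    * (frac[1] if dj else 1 - frac[1])
                    * (frac[2] if dk else 1 - frac[2])
                )
                ii = min(max(base[0] + di, 0), data.shape[0] - 1)
                jj = min(max(base[1] + dj, 0), data.shape[1] - 1)
                kk = min(max(base[2] + dk, 0), data.shape[2] - 1)
                val += w * data[ii, jj, kk]
    return val
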