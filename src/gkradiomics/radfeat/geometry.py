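"""Shape and size features of a binary lesion mask.

Volume is voxel counting; surface area counts exposed voxel faces (a
deterministic, oracle-checkable convention that overestimates the area of
smooth shapes relative to meshing).  The maximum 3D diameter is the largest
pairwise Euclidean distance between surface-voxel centers.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist


def _exposed_faces(mask: np.ndarray, spacing) -> tuple[float, np.ndarray]:
    """(total exposed-face area, boolean surface-voxel array)."""
    mask = np.asarray(mask, dtype=bool)
    area = 0.0
    surface = np.zeros_like(mask)
    face_area = [
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    ]
    for axis in range(3):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        lo = np.take(padded, range(0, mask.shape[axis]), axis=axis)
        hi = np.take(padded, range(2, mask.shape[axis] + 2), axis=axis)
        exposed = mask & ~lo
        area += exposed.sum() * face_area[axis]
        surface |= exposed
        exposed = mask & ~hi
        area += exposed.sum() * face_area[axis]
        surface |= exposed
    return float(area), surface


def geometry_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """The 8 registry geometry features of one mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    n = int(mask.sum())
    volume = n * float(np.prod(spacing))
    area, surface = _exposed_faces(mask, spacing)

    coords = np.argwhere(surface) * np.asarray(spacing)
    if len(coords) == 1:
        max_diam = 0.0
    else:
        if len(coords) > 400:
            # pairwise distances only over hull vertices — same maximum
            try:
                coords = coords[ConvexHull(coords).vertices]
            except Exception:  # degenerate (coplanar) point sets
                pass
        max_diam = float(pdist(coords).max())

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * r_equiv**2
    return {
        "volume_mm3": volume,
        "surface_area_mm2": area,
        "surface_to_volume": area / volume,
        "sphericity": sphere_area / area,
        "compactness1": volume / (np.sqrt(np.pi) * area**1.5),
        "compactness2": 36.0 * np.pi * volume**2 / area**3,
        "spherical_disproportion": area / sphere_area,
        "max_diameter_mm": max_diam,
    }
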