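"""3D image container and NIfTI I/O.

An :class:`ImageVolume` is a scalar 3D grid with per-axis voxel spacing, an
optional MR contrast tag (``T1w``, ``T1c``, ``T2w``) and a grid-to-world
mapping (origin + direction cosines).  Arrays are stored in ``(i, j, k)``
index order; the NIfTI affine maps index to world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

CONTRASTS = ("T1w", "T1c", "T2w")


@dataclass
class ImageVolume:
    data: np.ndarray
    spacing: tuple[float, float, float]
    contrast: str | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel data must be finite everywhere")
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Copy of this volume with replaced voxel data on the same grid."""
        return replace(self, data=np.asarray(data))

    # ------------------------------------------------------------------ #
    # conversions
    # ------------------------------------------------------------------ #
    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_sitk(self) -> sitk.Image:
        # SimpleITK arrays are (z, y, x); our storage is (i, j, k) = (x, y, z)
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(self.data, (2, 1, 0))))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, contrast: str | None = None) -> "ImageVolume":
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(
            data=data,
            spacing=tuple(img.GetSpacing()),
            contrast=contrast,
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )

    # ------------------------------------------------------------------ #
    # NIfTI I/O
    # ------------------------------------------------------------------ #
    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path, contrast: str | None = None) -> "ImageVolume":
        img = nib.load(str(path))
        aff = img.affine
        m = aff[:3, :3]
        spacing = tuple(np.linalg.norm(m, axis=0))
        direction = m / np.asarray(spacing)[None, :]
        return cls(
            data=np.asarray(img.get_fdata()),
            spacing=spacing,
            contrast=contrast,
            origin=tuple(aff[:3, 3]),
            direction=direction,
        )
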