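"""MRI preprocessing: isotropic resampling, rigid co-registration, Z-score.

The stage order is resample -> register (T1w/T2w onto the T1c grid) ->
Z-score, so registration operates on common grids and both native and
registered images are standardized identically.  Lesion masks are resampled
with nearest-neighbour interpolation and are never fractionally interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .image import ImageVolume

logger = logging.getLogger(__name__)

# Mutual information (negated by SimpleITK) above this value after
# convergence indicates the pair shares essentially no structure.
MI_QUALITY_THRESHOLD = -0.05


@dataclass
class RigidTransform:
    """Six-parameter rigid body transform: 3 Euler angles + 3 translations."""

    rotation: tuple[float, float, float]  # radians
    translation: tuple[float, float, float]  # mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center)
        t.SetRotation(*self.rotation)
        t.SetTranslation(self.translation)
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        return cls(
            rotation=(t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()),
            translation=tuple(t.GetTranslation()),
            center=tuple(t.GetCenter()),
        )


@dataclass
class RegistrationResult:
    transform: RigidTransform
    registered: ImageVolume
    final_metric: float
    quality_ok: bool
    iterations: int


# ---------------------------------------------------------------------- #
# resampling
# ---------------------------------------------------------------------- #
def resample_isotropic(
    vol: ImageVolume, target_mm: float | tuple = 1.0, is_mask: bool = False
) -> ImageVolume:
    """Resample to the target voxel size (trilinear; nearest for masks).

    The output grid covers the full physical extent of the input.  With
    target equal to the input spacing the volume is returned unchanged.
    """
    if np.isscalar(target_mm):
        target = (float(target_mm),) * 3
    else:
        target = tuple(float(t) for t in target_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if np.allclose(vol.spacing, target):
        return vol
    img = vol.to_sitk()
    new_size = [
        int(np.ceil(sz * sp / t)) for sz, sp, t in zip(img.GetSize(), img.GetSpacing(), target)
    ]
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear,
        img.GetOrigin(),
        target,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    return ImageVolume.from_sitk(out, contrast=vol.contrast)


# ---------------------------------------------------------------------- #
# rigid registration
# ---------------------------------------------------------------------- #
def rigid_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    n_bins: int = 32,
    max_iterations: int = 200,
    seed: int = 12345,
) -> RegistrationResult:
    """Mutual-information rigid registration of ``moving`` onto ``fixed``.

    Six-parameter (Euler angles + translation) transform optimized with a
    multi-resolution scheme and Mattes mutual information with ``n_bins``
    histogram bins.  Returns the transform, the moving image resampled into
    the fixed grid, and the final metric value; ``quality_ok`` is False when
    the converged metric indicates no shared structure (e.g. unrelated
    images), replacing the visual QC a human reader would perform.
    """
    f = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    m = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)

    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(0.25, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=max_iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)

    try:
        final = reg.Execute(f, m)
    except RuntimeError as exc:  # pragma: no cover - sitk failure path
        raise RuntimeError(f"rigid registration failed: {exc}") from exc

    final_metric = reg.GetMetricValue()
    iterations = reg.GetOptimizerIteration()
    concrete = final.Downcast()
    if isinstance(concrete, sitk.CompositeTransform):
        concrete = concrete.GetNthTransform(0).Downcast()
    transform = RigidTransform.from_sitk(sitk.Euler3DTransform(concrete))
    registered = sitk.Resample(m, f, final, sitk.sitkLinear, 0.0, sitk.sitkFloat32)
    quality_ok = final_metric < MI_QUALITY_THRESHOLD
    logger.info(
        "rigid_register: MI=%.4f iterations=%d rotation=%s translation=%s quality_ok=%s",
        final_metric,
        iterations,
        np.round(transform.rotation, 4),
        np.round(transform.translation, 3),
        quality_ok,
    )
    return RegistrationResult(
        transform=transform,
        registered=ImageVolume.from_sitk(registered, contrast=moving.contrast),
        final_metric=float(final_metric),
        quality_ok=quality_ok,
        iterations=int(iterations),
    )


def apply_rigid(vol: ImageVolume, transform: RigidTransform, reference: ImageVolume, is_mask: bool = False) -> ImageVolume:
    """Resample ``vol`` through ``transform`` into the reference grid."""
    out = sitk.Resample(
        vol.to_sitk(),
        reference.to_sitk(),
        transform.to_sitk(),
        sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear,
        0.0,
        sitk.sitkFloat64,
    )
    return ImageVolume.from_sitk(out, contrast=vol.contrast)


# ---------------------------------------------------------------------- #
# intensity standardization
# ---------------------------------------------------------------------- #
def zscore_normalize(vol: ImageVolume) -> ImageVolume:
    """Whole-image Z-score: subtract the global mean, divide by the global SD.

    A constant volume maps to all zeros with a logged warning.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    sd = data.std()
    if sd == 0:
        logger.warning("zscore_normalize: constant volume (SD=0); output is all zeros")
        return vol.with_data(np.zeros_like(data))
    return vol.with_data((data - data.mean()) / sd)
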