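"""Synthetic multi-contrast phantom cohorts with planted outcome structure.

The generator emulates the data a radiosurgery radiomics study consumes:
per patient, three co-registered MR contrasts (T1w, T1c, T2w) on a common
isotropic grid; per lesion, an ellipsoidal binary mask, a baseline and
follow-up volume, and a latent binary outcome class.  The planted structure
is the one the downstream pipeline is meant to detect:

* lesions of the latent "poor" class carry higher intra-lesion texture
  heterogeneity (smoothed Gaussian noise of larger amplitude inside the
  mask), so texture features separate the classes;
* clinical covariates differ between classes by configurable standardized
  effect sizes, so a clinical-only model has nontrivial but imperfect power;
* follow-up lesion volumes are drawn so the >10% volume-increase rule
  recovers the latent class up to a configurable flip rate;
* overall survival is log-normal per class, so a median split recovers the
  class with known overlap.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import CONTRASTS, ImageVolume

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id",
    "lesion_id",
    "kps_ge90",
    "extracranial_mets",
    "primary_controlled",
    "n_lesions",
    "os_months",
    "vol_baseline_mm3",
    "vol_followup_mm3",
]


@dataclass
class PhantomSpec:
    """Configuration of one synthetic cohort.

    Parameters
    ----------
    grid_shape : voxels per axis of every volume.
    spacing_mm : voxel size per axis (the generator emits isotropic 1 mm by
        default, matching the resampling target of the preprocessing stage).
    n_patients : number of patients.
    lesions_per_patient : inclusive (lo, hi) range for the per-patient
        lesion count.
    lesion_radius_mm : inclusive (lo, hi) range for the nominal ellipsoid
        radius; per-axis radii are jittered +/-30% around the draw.
    heterogeneity_by_class : texture-noise amplitude inside the mask for the
        (good, poor) latent classes, in units of the lesion/background
        contrast step.  Equal values make the classes texture-indistinguishable.
    contrast_means : per-contrast (background, lesion) mean intensities.
    effect_sizes : standardized mean difference between outcome classes of
        the latent Gaussian behind each binary clinical covariate, keyed by
        covariate name; ``n_lesions_extra`` is the additive Poisson-rate
        increment for the poor class.
    poor_fraction : marginal probability of the latent poor class (patient
        level); lesions inherit their patient's class.
    label_flip_rate : probability that a lesion's follow-up volume is drawn
        from the opposite class's response distribution.
    os_median_months : per-class (good, poor) median overall survival.
    os_sigma : log-normal shape parameter shared by both classes.
    seed : RNG seed; fixed seed reproduces the cohort bit-for-bit.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_patients: int = 20
    lesions_per_patient: tuple[int, int] = (1, 3)
    lesion_radius_mm: tuple[float, float] = (3.0, 6.0)
    heterogeneity_by_class: tuple[float, float] = (0.15, 0.9)
    contrast_means: dict = field(
        default_factory=lambda: {
            "T1w": (0.3, 0.8),
            "T1c": (0.3, 1.2),
            "T2w": (0.5, 1.0),
        }
    )
    effect_sizes: dict = field(
        default_factory=lambda: {
            "kps_ge90": 0.8,
            "extracranial_mets": 0.8,
            "primary_controlled": 0.5,
            "n_lesions_extra": 1.5,
        }
    )
    poor_fraction: float = 0.35
    label_flip_rate: float = 0.0
    os_median_months: tuple[float, float] = (20.0, 7.0)
    os_sigma: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid lesions_per_patient range {self.lesions_per_patient}")
        rmax = self.lesion_radius_mm[1] * 1.3
        half_extent = min(
            g * s / 2.0 for g, s in zip(self.grid_shape, self.spacing_mm)
        )
        if rmax >= half_extent:
            raise ValueError(
                f"largest jittered lesion radius {rmax:.1f} mm does not fit inside "
                f"the grid (half-extent {half_extent:.1f} mm)"
            )
        if not 0.0 <= self.label_flip_rate <= 1.0:
            raise ValueError("label_flip_rate must be in [0, 1]")


@dataclass
class Lesion:
    patient_id: str
    lesion_id: str
    mask: np.ndarray  # boolean, full grid
    latent_class: int  # 0 = good, 1 = poor
    vol_baseline_mm3: float
    vol_followup_mm3: float


@dataclass
class Patient:
    patient_id: str
    volumes: dict  # contrast -> ImageVolume
    lesions: list
    latent_class: int
    clinical: dict  # covariate name -> value (incl. os_months)


@dataclass
class SyntheticCohort:
    spec: PhantomSpec
    patients: list

    @property
    def lesions(self) -> list:
        return [les for p in self.patients for les in p.lesions]

    def clinical_table(self) -> pd.DataFrame:
        """Lesion-wise clinical table (one row per lesion)."""
        rows = []
        for p in self.patients:
            for les in p.lesions:
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "lesion_id": les.lesion_id,
                        "kps_ge90": p.clinical["kps_ge90"],
                        "extracranial_mets": p.clinical["extracranial_mets"],
                        "primary_controlled": p.clinical["primary_controlled"],
                        "n_lesions": p.clinical["n_lesions"],
                        "os_months": p.clinical["os_months"],
                        "vol_baseline_mm3": les.vol_baseline_mm3,
                        "vol_followup_mm3": les.vol_followup_mm3,
                    }
                )
        return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)

    def latent_classes(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "lesion_id": les.lesion_id,
                "patient_class": p.latent_class,
                "lesion_class": les.latent_class,
            }
            for p in self.patients
            for les in p.lesions
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# generation
# ---------------------------------------------------------------------- #
def _smooth_noise(rng: np.random.Generator, shape, corr_len: float = 2.0) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with ~corr_len voxel correlation."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_len / 2.0)
    sd = field_.std()
    if sd == 0:
        return field_
    return (field_ - field_.mean()) / sd


def _ellipsoid_mask(shape, spacing, center_vox, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(
        ((g - c) * s / r) ** 2
        for g, c, s, r in zip(grids, center_vox, spacing, radii_mm)
    )
    return d2 <= 1.0


def _place_lesions(rng, spec: PhantomSpec, n_lesions: int, patient_id: str):
    """Non-overlapping ellipsoid masks; bounded retries per lesion."""
    shape = tuple(spec.grid_shape)
    spacing = spec.spacing_mm
    occupied = np.zeros(shape, dtype=bool)
    masks, radii_list = [], []
    for _ in range(n_lesions):
        for attempt in range(200):
            r0 = rng.uniform(*spec.lesion_radius_mm)
            radii = r0 * rng.uniform(0.7, 1.3, size=3)
            margin_vox = [int(np.ceil(r / s)) + 2 for r, s in zip(radii, spacing)]
            if any(2 * m >= n for m, n in zip(margin_vox, shape)):
                continue
            center = [rng.integers(m, n - m) for m, n in zip(margin_vox, shape)]
            mask = _ellipsoid_mask(shape, spacing, center, radii)
            if mask.any() and not (mask & occupied).any():
                occupied |= mask
                masks.append(mask)
                radii_list.append(radii)
                break
        else:
            raise RuntimeError(
                f"failed to place lesion {len(masks) + 1} for patient {patient_id} "
                f"after 200 attempts"
            )
    return masks, radii_list


def _binary_covariate(rng, n, classes, effect_size):
    """Binary covariate from a thresholded latent Gaussian shifted by class."""
    latent = rng.standard_normal(n) + effect_size * (0.5 - classes)
    return (latent > 0).astype(int)


def make_phantom_cohort(spec: PhantomSpec) -> SyntheticCohort:
    """Generate one synthetic cohort per the planted-effect design above."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    # fixed class quota (not iid draws): prevalence is a design parameter,
    # and a poor_fraction of 0.5 makes the median-OS split exactly
    # class-consistent under the rank matching below
    n_poor = int(round(spec.poor_fraction * n))
    classes = np.zeros(n, dtype=int)
    classes[:n_poor] = 1
    rng.shuffle(classes)

    kps = _binary_covariate(rng, n, classes, spec.effect_sizes.get("kps_ge90", 0.0))
    # extracranial metastases are MORE likely in the poor class
    ecm = 1 - _binary_covariate(rng, n, classes, spec.effect_sizes.get("extracranial_mets", 0.0))
    primary = _binary_covariate(rng, n, classes, spec.effect_sizes.get("primary_controlled", 0.0))

    med_good, med_poor = spec.os_median_months
    patients = []
    for i in range(n):
        pid = f"P{i:03d}"
        cls = int(classes[i])
        n_les = int(rng.integers(spec.lesions_per_patient[0], spec.lesions_per_patient[1] + 1))
        n_les += rng.poisson(spec.effect_sizes.get("n_lesions_extra", 0.0) * cls)
        masks, _ = _place_lesions(rng, spec, n_les, pid)

        shape = tuple(spec.grid_shape)
        volumes = {}
        # shared anatomy field so the three contrasts are genuinely co-registered
        anatomy = _smooth_noise(rng, shape, corr_len=6.0)
        union = np.zeros(shape, dtype=bool)
        for m in masks:
            union |= m
        hetero_fields = [_smooth_noise(rng, shape, corr_len=2.0) for _ in masks]
        amp = spec.heterogeneity_by_class[cls]
        for contrast in CONTRASTS:
            bg_mean, les_mean = spec.contrast_means[contrast]
            data = bg_mean + 0.05 * anatomy + 0.02 * rng.standard_normal(shape)
            data[union] = les_mean
            step = abs(les_mean - bg_mean) or 1.0
            for m, hf in zip(masks, hetero_fields):
                data[m] += amp * step * hf[m]
            volumes[contrast] = ImageVolume(
                data=data.astype(np.float64), spacing=spec.spacing_mm, contrast=contrast
            )

        vox_mm3 = float(np.prod(spec.spacing_mm))
        lesions = []
        for j, m in enumerate(masks):
            baseline = float(m.sum()) * vox_mm3
            eff_cls = cls
            if rng.random() < spec.label_flip_rate:
                eff_cls = 1 - eff_cls
            # poor control: >10% growth; good: stable or shrinking
            ratio = rng.uniform(1.15, 2.0) if eff_cls == 1 else rng.uniform(0.5, 1.05)
            lesions.append(
                Lesion(
                    patient_id=pid,
                    lesion_id=f"{pid}-L{j:02d}",
                    mask=m,
                    latent_class=cls,
                    vol_baseline_mm3=baseline,
                    vol_followup_mm3=baseline * ratio,
                )
            )

        os_cls = cls
        if rng.random() < spec.label_flip_rate:
            os_cls = 1 - os_cls
        median = med_poor if os_cls == 1 else med_good
        os_months = float(rng.lognormal(mean=np.log(median), sigma=spec.os_sigma))
        clinical = {
            "kps_ge90": int(kps[i]),
            "extracranial_mets": int(ecm[i]),
            "primary_controlled": int(primary[i]),
            "n_lesions": n_les,
            "os_months": os_months,
        }
        patients.append(
            Patient(patient_id=pid, volumes=volumes, lesions=lesions, latent_class=cls, clinical=clinical)
        )

    if spec.label_flip_rate == 0.0:
        # rank-match overall survival to the latent classes: poor patients
        # receive the lowest OS ranks, so a median split is exactly
        # class-consistent whenever the class quota is n/2
        os_sorted = np.sort([p.clinical["os_months"] for p in patients])
        poor = [p for p in patients if p.latent_class == 1]
        good = [p for p in patients if p.latent_class == 0]
        for p, v in zip(poor + good, os_sorted):
            p.clinical["os_months"] = float(v)
    return SyntheticCohort(spec=spec, patients=patients)


# ---------------------------------------------------------------------- #
# persistence
# ---------------------------------------------------------------------- #
def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write NIfTI volumes/masks, the clinical CSV and a JSON manifest.

    Returns the manifest path; :func:`read_cohort` round-trips the output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"spec_seed": cohort.spec.seed, "patients": []}
    for p in cohort.patients:
        entry = {"patient_id": p.patient_id, "latent_class": p.latent_class, "volumes": {}, "lesions": []}
        for contrast, vol in p.volumes.items():
            fname = f"{p.patient_id}_{contrast}.nii.gz"
            vol.save(out / fname)
            entry["volumes"][contrast] = fname
        for les in p.lesions:
            fname = f"{les.lesion_id}_mask.nii.gz"
            spacing = p.volumes["T1c"].spacing if p.volumes else cohort.spec.spacing_mm
            ImageVolume(data=les.mask.astype(np.float32), spacing=spacing).save(out / fname)
            entry["lesions"].append(
                {
                    "lesion_id": les.lesion_id,
                    "mask": fname,
                    "latent_class": les.latent_class,
                    "vol_baseline_mm3": les.vol_baseline_mm3,
                    "vol_followup_mm3": les.vol_followup_mm3,
                }
            )
        manifest["patients"].append(entry)
    cohort.clinical_table().to_csv(out / "clinical.csv", index=False)
    manifest["clinical_csv"] = "clinical.csv"
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(manifest_path) -> SyntheticCohort:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    clinical = pd.read_csv(root / manifest["clinical_csv"]) if manifest["patients"] else pd.DataFrame(columns=CLINICAL_COLUMNS)
    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        volumes = {
            c: ImageVolume.load(root / fn, contrast=c) for c, fn in entry["volumes"].items()
        }
        lesions = []
        for les in entry["lesions"]:
            mask_vol = ImageVolume.load(root / les["mask"])
            lesions.append(
                Lesion(
                    patient_id=pid,
                    lesion_id=les["lesion_id"],
                    mask=mask_vol.data > 0.5,
                    latent_class=les["latent_class"],
                    vol_baseline_mm3=les["vol_baseline_mm3"],
                    vol_followup_mm3=les["vol_followup_mm3"],
                )
            )
        prow = clinical[clinical.patient_id == pid].iloc[0]
        patients.append(
            Patient(
                patient_id=pid,
                volumes=volumes,
                lesions=lesions,
                latent_class=entry["latent_class"],
                clinical={
                    "kps_ge90": int(prow.kps_ge90),
                    "extracranial_mets": int(prow.extracranial_mets),
                    "primary_controlled": int(prow.primary_controlled),
                    "n_lesions": int(prow.n_lesions),
                    "os_months": float(prow.os_months),
                },
            )
        )
    # spec is not fully recoverable from disk; store seed only
    spec = PhantomSpec(seed=manifest.get("spec_seed", 0))
    return SyntheticCohort(spec=spec, patients=patients)
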