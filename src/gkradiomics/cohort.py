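"""Outcome labeling and modeling-table assembly.

Two binary outcomes are supported:

* **local tumor control** (lesion-wise): a lesion is labeled *poor*
  (progression) when its follow-up volume exceeds baseline by more than
  10%; stable or regressing lesions are *good*.  Exactly +10% is good.
* **overall survival** (patient-wise): patients at or above the cohort
  median survival are *good*; below it, *poor*.  Survival models use only
  the radiomic features of each patient's largest (baseline-volume) lesion.

Labels are encoded poor=1 (the positive class for sensitivity), good=0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GOOD, POOR = 0, 1
TASKS = ("local_control", "survival")
CLINICAL_FEATURES = [
    "kps_ge90",
    "extracranial_mets",
    "primary_controlled",
    "n_lesions",
    "log_volume_mm3",
]
PROGRESSION_THRESHOLD = 0.10


def label_tumor_control(vol_baseline_mm3: float, vol_followup_mm3: float) -> int:
    """Volume-change rule: >10% growth -> poor (1); otherwise good (0)."""
    if vol_baseline_mm3 <= 0 or vol_followup_mm3 <= 0:
        raise ValueError(
            f"volumes must be positive, got baseline={vol_baseline_mm3}, "
            f"followup={vol_followup_mm3}"
        )
    delta = (vol_followup_mm3 - vol_baseline_mm3) / vol_baseline_mm3
    return POOR if delta > PROGRESSION_THRESHOLD else GOOD


def label_survival(os_months: float, cohort_median_months: float) -> int:
    """Median split: OS >= cohort median -> good (0); below -> poor (1)."""
    if os_months < 0:
        raise ValueError(f"overall survival must be >= 0, got {os_months}")
    return GOOD if os_months >= cohort_median_months else POOR


def largest_bm_per_patient(records: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: the lesion with maximal baseline volume.

    Ties are broken toward the lexicographically smallest lesion_id (logged).
    ``records`` needs columns patient_id, lesion_id, vol_baseline_mm3.
    """
    if records.empty:
        raise ValueError("no lesion records")
    out_rows = []
    for pid, grp in records.groupby("patient_id", sort=True):
        vmax = grp["vol_baseline_mm3"].max()
        best = grp[grp["vol_baseline_mm3"] == vmax].sort_values("lesion_id")
        if len(best) > 1:
            logger.info(
                "largest_bm_per_patient: tie at %.1f mm3 for patient %s; keeping %s",
                vmax, pid, best.iloc[0]["lesion_id"],
            )
        out_rows.append(best.iloc[0])
    return pd.DataFrame(out_rows).reset_index(drop=True)


def assemble_table(
    clinical: pd.DataFrame,
    features: pd.DataFrame,
    task: str,
) -> pd.DataFrame:
    """Labeled modeling table for one task.

    Parameters
    ----------
    clinical : lesion-wise table with the ``synthgen`` clinical columns
        (one row per lesion; patient covariates repeated across lesions).
    features : radiomic feature table indexed by (patient_id, lesion_id).
    task : ``local_control`` (lesion-wise rows) or ``survival``
        (patient-wise rows via the largest-lesion rule).

    Returns a DataFrame with columns patient_id, lesion_id, the encoded
    clinical covariates, every radiomic feature, and ``label``; the
    clinical/radiomics/combined column subsets are given by
    :func:`view_columns`.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    df = clinical.copy()
    required = {"patient_id", "lesion_id", "vol_baseline_mm3", "vol_followup_mm3", "os_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")

    if task == "survival":
        df = largest_bm_per_patient(df)
        median = float(np.median(df["os_months"]))
        df["label"] = [label_survival(v, median) for v in df["os_months"]]
    else:
        df["label"] = [
            label_tumor_control(b, f)
            for b, f in zip(df["vol_baseline_mm3"], df["vol_followup_mm3"])
        ]
    df["log_volume_mm3"] = np.log(df["vol_baseline_mm3"].to_numpy(dtype=float))

    feat = features.reset_index()
    merged = df.merge(feat, on=["patient_id", "lesion_id"], how="left", validate="1:1")
    radiomic_cols = list(features.columns)
    model_cols = CLINICAL_FEATURES + radiomic_cols + ["label"]
    bad = merged[model_cols].isna().any(axis=1)
    if bad.any():
        ids = merged.loc[bad, ["patient_id", "lesion_id"]].to_records(index=False).tolist()
        raise ValueError(f"missing covariates/features for units {ids[:10]}")
    keep = ["patient_id", "lesion_id"] + CLINICAL_FEATURES + radiomic_cols + ["label"]
    out = merged[keep].reset_index(drop=True)
    out.attrs["task"] = task
    out.attrs["radiomic_columns"] = radiomic_cols
    return out


def view_columns(table: pd.DataFrame, view: str) -> list[str]:
    """Feature columns of the clinical / radiomics / combined view."""
    radiomic = table.attrs.get("radiomic_columns")
    if radiomic is None:
        radiomic = [c for c in table.columns if c.count(".") >= 2]
    if view == "clinical":
        return list(CLINICAL_FEATURES)
    if view == "radiomics":
        return list(radiomic)
    if view == "combined":
        return list(CLINICAL_FEATURES) + list(radiomic)
    raise ValueError(f"unknown view {view!r}")
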