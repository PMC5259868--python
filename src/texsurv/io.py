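"""Reading and writing cohorts: NIfTI lesion slices plus a clinical table.

Layout of a cohort directory::

    <patient>_<lesion>_<baseline|followup>_img.nii.gz   float32 HU slice
    <patient>_<lesion>_<baseline|followup>_mask.nii.gz  0/1 ROI mask
    clinical.csv                                        one row per lesion-timepoint
    ground_truth.json                                   generator latents (synthetic cohorts)
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import IMDC_GROUPS, LesionImage, PatientRecord, TIMEPOINTS

CLINICAL_COLUMNS = [
    "patient_id",
    "imdc_group",
    "lesion_id",
    "organ",
    "timepoint",
    "longest_diameter_mm",
    "is_primary",
    "os_days",
    "os_event",
    "pfs_days",
    "pfs_event",
]


def _nifti_name(lesion: LesionImage, kind: str) -> str:
    return f"{lesion.patient_id}_{lesion.lesion_id}_{lesion.timepoint}_{kind}.nii.gz"


def _save_slice(path: Path, data: np.ndarray, spacing: float) -> None:
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_cohort(records: list[PatientRecord], directory) -> dict:
    """Write every lesion image/mask, the clinical CSV and ground truth stub.

    Returns a manifest of the files written.  Refuses an empty cohort.
    """
    if not records:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    images, rows = [], []
    for rec in records:
        for lesion in rec.lesions:
            img_path = directory / _nifti_name(lesion, "img")
            mask_path = directory / _nifti_name(lesion, "mask")
            _save_slice(img_path, lesion.pixels.astype(np.float32), lesion.pixel_spacing_mm)
            _save_slice(mask_path, lesion.mask.astype(np.uint8), lesion.pixel_spacing_mm)
            images += [img_path, mask_path]
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "imdc_group": rec.imdc_group,
                    "lesion_id": lesion.lesion_id,
                    "organ": lesion.organ,
                    "timepoint": lesion.timepoint,
                    "longest_diameter_mm": lesion.longest_diameter_mm,
                    "is_primary": int(lesion.is_primary),
                    "os_days": rec.os_days,
                    "os_event": rec.os_event,
                    "pfs_days": rec.pfs_days,
                    "pfs_event": rec.pfs_event,
                }
            )
    clinical = directory / "clinical.csv"
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(clinical, index=False)
    return {"images": [str(p) for p in images], "clinical": str(clinical)}


def write_ground_truth(truth, directory) -> str:
    path = Path(directory) / "ground_truth.json"
    with open(path, "w") as fh:
        json.dump(truth.as_dict(), fh, indent=1)
    return str(path)


def read_cohort(directory) -> list[PatientRecord]:
    """Load a cohort directory back into patient records with lesion images."""
    directory = Path(directory)
    clinical = directory / "clinical.csv"
    if not clinical.exists():
        raise FileNotFoundError(f"no clinical.csv in {directory}")
    table = pd.read_csv(clinical)

    records: dict[str, PatientRecord] = {}
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        if pid not in records:
            if row["imdc_group"] not in IMDC_GROUPS:
                raise ValueError(f"unknown IMDC group {row['imdc_group']!r}")
            records[pid] = PatientRecord(
                patient_id=pid,
                imdc_group=row["imdc_group"],
                os_days=float(row["os_days"]),
                os_event=int(row["os_event"]),
                pfs_days=float(row["pfs_days"]),
                pfs_event=int(row["pfs_event"]),
            )
        timepoint = str(row["timepoint"])
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        stem = f"{pid}_{row['lesion_id']}_{timepoint}"
        img = nib.load(str(directory / f"{stem}_img.nii.gz"))
        mask = nib.load(str(directory / f"{stem}_mask.nii.gz"))
        spacing = float(img.header.get_zooms()[0])
        records[pid].lesions.append(
            LesionImage(
                pixels=np.asanyarray(img.dataobj, dtype=np.float32),
                mask=np.asanyarray(mask.dataobj) > 0,
                pixel_spacing_mm=spacing,
                patient_id=pid,
                lesion_id=str(row["lesion_id"]),
                organ=str(row["organ"]),
                timepoint=timepoint,
                longest_diameter_mm=float(row["longest_diameter_mm"]),
                is_primary=bool(row.get("is_primary", 0)),
            )
        )
    return list(records.values())
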