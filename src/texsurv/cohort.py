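"""Patient-level assembly: target-lesion selection, feature averaging and
change biomarkers.

Target lesions follow the RECIST 1.1 measurability rules used in the study:
lesions under 10 mm longest diameter are not measurable, at most two lesions
per organ and five overall are kept (largest first), and an unresected
primary tumor is always retained.  Per-patient features are the unweighted
mean of the selected lesions' features at each timepoint; treatment response
is summarized by percent change (with a +3 shift for kurtosis and a plain
difference for skewness, both guarding against zero denominators) and by the
percent reduction in the sum of longest diameters.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .texture import (
    DEFAULT_HU_HIGH,
    DEFAULT_HU_LOW,
    DEFAULT_N_BINS,
    FilterSpec,
    UnusableROIError,
    extract_features,
)
from .types import BASELINE, FOLLOWUP, LesionImage, PatientRecord, TextureFeatures

logger = logging.getLogger(__name__)

MIN_TARGET_DIAMETER_MM = 10.0
MAX_LESIONS_PER_ORGAN = 2
MAX_TARGET_LESIONS = 5


class UnmeasurablePatientError(ValueError):
    """No lesion satisfies the 10 mm measurability floor."""


def select_target_lesions(lesions: list[LesionImage]) -> list[LesionImage]:
    """Apply the target-lesion rules to one patient's baseline lesions.

    Returns the selected subset, largest diameters first.  Ties are broken by
    lesion_id lexicographic order.  If keeping the unresected primary plus the
    per-organ survivors would exceed five, the primary displaces the smallest
    non-primary lesion.
    """
    eligible = [l for l in lesions if l.longest_diameter_mm >= MIN_TARGET_DIAMETER_MM]
    n_dropped = len(lesions) - len(eligible)
    if n_dropped:
        logger.info("dropped %d lesion(s) under %.0f mm", n_dropped, MIN_TARGET_DIAMETER_MM)
    if not eligible:
        raise UnmeasurablePatientError("no measurable lesion >= 10 mm")

    key = lambda l: (-l.longest_diameter_mm, l.lesion_id)
    primaries = sorted((l for l in eligible if l.is_primary), key=key)

    survivors: list[LesionImage] = []
    by_organ: dict[str, list[LesionImage]] = {}
    for lesion in sorted((l for l in eligible if not l.is_primary), key=key):
        by_organ.setdefault(lesion.organ, []).append(lesion)
    for organ, group in by_organ.items():
        allowance = MAX_LESIONS_PER_ORGAN - sum(1 for p in primaries if p.organ == organ)
        survivors.extend(group[: max(allowance, 0)])

    n_free = max(MAX_TARGET_LESIONS - len(primaries), 0)
    selected = primaries + sorted(survivors, key=key)[:n_free]
    return sorted(selected, key=key)


def average_features(features: list[TextureFeatures]) -> TextureFeatures:
    """Unweighted mean of per-lesion features; missing values dropped pairwise.

    n_pixels is reported as the sum over lesions.  A feature missing in every
    lesion stays missing at patient level.
    """
    if not features:
        raise ValueError("average_features requires at least one lesion")

    def _nanmean(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return TextureFeatures(
        mpp=_nanmean([f.mpp for f in features]),
        sd=_nanmean([f.sd for f in features]),
        skewness=_nanmean([f.skewness for f in features]),
        kurtosis=_nanmean([f.kurtosis for f in features]),
        entropy_bits=_nanmean([f.entropy_bits for f in features]),
        nsd=_nanmean([f.nsd for f in features]),
        n_pixels=int(sum(f.n_pixels for f in features)),
    )


def percent_change(pre: float, post: float, feature_name: str) -> float:
    """Percent change of a texture parameter between baseline and follow-up.

    Default: (post - pre)/pre x 100.  Kurtosis values are shifted by +3
    before the ratio (kurtosis ranges through 0, which would divide by zero);
    skewness uses the plain difference post - pre for the same reason.
    A zero denominator after any shift yields NaN (missing), not an error.
    """
    name = feature_name.lower()
    if math.isnan(pre) or math.isnan(post):
        return float("nan")
    if "skew" in name:
        return post - pre
    if "kurt" in name:
        pre, post = pre + 3.0, post + 3.0
    if pre == 0:
        return float("nan")
    return (post - pre) / pre * 100.0


def size_percent_change(baseline_sum_mm: float, followup_sum_mm: float) -> float:
    """Percent reduction in the sum of longest diameters (shrinkage positive)."""
    if baseline_sum_mm <= 0:
        raise ValueError("baseline diameter sum must be positive")
    return (baseline_sum_mm - followup_sum_mm) / baseline_sum_mm * 100.0


# ---------------------------------------------------------------------------
# table-level assembly

#: change-biomarker columns and the per-timepoint feature they derive from
CHANGE_COLUMNS = {
    "perc_mpp": "mpp",
    "perc_sd": "sd",
    "perc_entropy": "entropy_bits",
    "perc_nsd": "nsd",
    "perc_kurtosis": "kurtosis",
    "delta_skewness": "skewness",
}

FEATURE_SHORT = {"mpp": "mpp", "sd": "sd", "entropy_bits": "entropy",
                 "nsd": "nsd", "kurtosis": "kurtosis", "skewness": "skewness"}


def extract_lesion_table(
    records: list[PatientRecord],
    spec: FilterSpec = FilterSpec(),
    hu_low: float = DEFAULT_HU_LOW,
    hu_high: float = DEFAULT_HU_HIGH,
    n_bins: int = DEFAULT_N_BINS,
) -> pd.DataFrame:
    """Filtration-histogram features for every lesion at every timepoint."""
    rows = []
    for rec in records:
        for lesion in rec.lesions:
            try:
                feats = extract_features(lesion, spec, hu_low, hu_high, n_bins)
            except UnusableROIError:
                logger.warning(
                    "patient %s lesion %s (%s): unusable ROI after HU refinement",
                    rec.patient_id, lesion.lesion_id, lesion.timepoint,
                )
                continue
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "lesion_id": lesion.lesion_id,
                    "timepoint": lesion.timepoint,
                    "organ": lesion.organ,
                    **feats.as_dict(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "lesion_id", "timepoint", "organ",
                 "mpp", "sd", "skewness", "kurtosis", "entropy_bits", "nsd", "n_pixels"],
    )


def build_patient_table(
    records: list[PatientRecord], lesion_features: pd.DataFrame
) -> pd.DataFrame:
    """Patient-level analysis table: averaged features at each timepoint, the
    six change biomarkers, the RECIST size change and the survival columns.

    Patients with no measurable lesion are dropped with a logged warning.
    """
    rows = []
    for rec in records:
        baselines = rec.lesions_at(BASELINE)
        if not baselines:
            logger.warning("patient %s: no baseline lesions; skipped", rec.patient_id)
            continue
        try:
            selected = select_target_lesions(baselines)
        except UnmeasurablePatientError:
            logger.warning("patient %s: unmeasurable (all lesions < 10 mm)", rec.patient_id)
            continue
        selected_ids = [l.lesion_id for l in selected]
        followups = {l.lesion_id: l for l in rec.lesions_at(FOLLOWUP)}

        feats = lesion_features[lesion_features["patient_id"] == rec.patient_id]
        row = {"patient_id": rec.patient_id, "imdc_group": rec.imdc_group,
               "n_lesions_selected": len(selected_ids)}
        for timepoint, suffix in ((BASELINE, "pre"), (FOLLOWUP, "post")):
            sub = feats[(feats["timepoint"] == timepoint) & feats["lesion_id"].isin(selected_ids)]
            for col, short in FEATURE_SHORT.items():
                vals = sub[col].to_numpy(dtype=float) if len(sub) else np.array([])
                vals = vals[~np.isnan(vals)]
                row[f"{short}_{suffix}"] = float(vals.mean()) if vals.size else float("nan")

        for change_col, feature in CHANGE_COLUMNS.items():
            short = FEATURE_SHORT[feature]
            row[change_col] = percent_change(
                row[f"{short}_pre"], row[f"{short}_post"], feature
            )

        base_sum = sum(l.longest_diameter_mm for l in selected)
        fu = [followups[i] for i in selected_ids if i in followups]
        if fu and base_sum > 0:
            fu_sum = sum(l.longest_diameter_mm for l in fu)
            row["size_percent_change"] = size_percent_change(base_sum, fu_sum)
        else:
            row["size_percent_change"] = float("nan")

        row.update(
            os_days=rec.os_days, os_event=rec.os_event,
            pfs_days=rec.pfs_days, pfs_event=rec.pfs_event,
        )
        rows.append(row)
    return pd.DataFrame(rows)
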