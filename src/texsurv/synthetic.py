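"""Synthetic lesion images and survival outcomes with known ground truth.

Lesion textures are Gaussian random fields: white noise smoothed to a
controllable correlation length and affinely rescaled so the ROI hits a
target mean and SD exactly.  Follow-up images apply a treatment-effect
transform (diameter shrinkage, SD rescaling, fresh acquisition noise).
Survival times come from a proportional-hazards mechanism whose log-hazard
is linear in the patient's mean baseline nSD and ordinal IMDC level, with
administrative right-censoring at a fixed horizon.

The generator exists so every downstream stage — filtration-histogram
features, lesion selection, change biomarkers, Cox/KM modelling — can be
validated at desk scale with a known generating model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .texture import nsd
from .types import BASELINE, FOLLOWUP, IMDC_GROUPS, LesionImage, PatientRecord

ORGAN_POOL = ("lymph node", "lung", "liver", "bone", "adrenal", "peritoneum")


@dataclass
class SimulationConfig:
    """Study-level knobs of the synthetic cohort.

    Defaults emulate a metastatic renal-cell carcinoma cohort on a TKI:
    ~40 patients with 1-4 target-sized lesions each, soft-tissue attenuation,
    strongly protective nSD (beta_nsd < 0: more heterogeneous-per-size tumors
    do better), prognostic IMDC, and follow-up truncated at ~22.8 months.
    """

    n_patients: int = 40
    lesions_per_patient: tuple = (1, 4)
    image_extent: int = 16          # minimum grid side, pixels (grid grows with lesion diameter)
    pixel_spacing_mm: float = 0.933
    mean_hu: float = 60.0
    sd_target_range: tuple = (10.0, 60.0)
    correlation_length_range: tuple = (0.5, 3.0)   # pixels
    diameter_range_mm: tuple = (12.0, 80.0)
    shrink_factor_range: tuple = (0.5, 1.2)
    sd_multiplier_range: tuple = (0.7, 1.3)
    imdc_probs: tuple = (0.25, 0.50, 0.25)
    beta_nsd: float = -5.0          # log-hazard per unit nSD
    beta_imdc: float = 0.7          # log-hazard per IMDC level (0/1/2)
    baseline_rate: float = 0.0074   # events per day at nSD = 0, IMDC good
    censor_days: float = 693.0      # ~22.8 months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if abs(sum(self.imdc_probs) - 1.0) > 1e-9:
            raise ValueError("imdc_probs must sum to 1")
        if min(self.imdc_probs) < 0 or max(self.imdc_probs) == 0:
            raise ValueError("imdc_probs must be non-negative, not all zero")
        if min(self.sd_target_range) <= 0:
            raise ValueError("sd_target_range must be strictly positive")
        if self.censor_days < 0:
            raise ValueError("censor_days must be non-negative")
        if not 0 < max(self.shrink_factor_range) <= 1.5:
            raise ValueError("shrink factors must lie in (0, 1.5]")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")


@dataclass
class GroundTruth:
    """Latent values of a generated cohort, for parameter-recovery checks."""

    beta_nsd: float
    beta_imdc: float
    baseline_rate: float
    censor_days: float
    seed: int
    patients: pd.DataFrame = field(repr=False)

    def as_dict(self) -> dict:
        d = {
            "beta_nsd": self.beta_nsd,
            "beta_imdc": self.beta_imdc,
            "baseline_rate": self.baseline_rate,
            "censor_days": self.censor_days,
            "seed": self.seed,
        }
        d["patients"] = self.patients.to_dict(orient="records")
        return d


def _ellipse_mask(extent: int, semi_major: float, semi_minor: float) -> np.ndarray:
    c = (extent - 1) / 2.0
    y, x = np.mgrid[0:extent, 0:extent].astype(np.float64)
    return ((x - c) / semi_major) ** 2 + ((y - c) / semi_minor) ** 2 <= 1.0


def gen_lesion_image(
    extent: int,
    mean_hu: float,
    sd_target: float,
    corr_len: float,
    seed: int,
    *,
    pixel_spacing_mm: float = 0.933,
    aspect: float | None = None,
    patient_id: str = "P000",
    lesion_id: str = "L00",
    organ: str = "lesion",
    timepoint: str = BASELINE,
    is_primary: bool = False,
) -> LesionImage:
    """Generate one lesion slice: a Gaussian random field under an ellipse ROI.

    The ROI is an axis-aligned ellipse inscribed in the grid (aspect ratio
    drawn uniformly in [0.6, 1] unless given).  White noise is smoothed with
    an isotropic Gaussian of SD ``corr_len`` pixels, then affinely rescaled so
    the ROI sample mean and SD equal ``mean_hu`` and ``sd_target``.
    Deterministic for a fixed seed.
    """
    if extent < 16:
        raise ValueError("extent must be >= 16 pixels")
    if sd_target <= 0:
        raise ValueError("sd_target must be positive")
    if corr_len < 0:
        raise ValueError("corr_len must be non-negative")

    rng = np.random.default_rng(seed)
    if aspect is None:
        aspect = float(rng.uniform(0.6, 1.0))
    semi_major = extent / 2.0 - 1.0
    semi_minor = aspect * semi_major
    if semi_major < 1.0:
        raise ValueError("extent too small to host an ellipse of >= 2 pixels")
    mask = _ellipse_mask(extent, semi_major, semi_minor)

    noise = rng.standard_normal((extent, extent))
    if corr_len > 0:
        noise = ndimage.gaussian_filter(noise, sigma=corr_len, mode="reflect")
    roi = noise[mask]
    pixels = mean_hu + (noise - roi.mean()) * (sd_target / roi.std(ddof=0))

    return LesionImage(
        pixels=pixels.astype(np.float32),
        mask=mask,
        pixel_spacing_mm=pixel_spacing_mm,
        patient_id=patient_id,
        lesion_id=lesion_id,
        organ=organ,
        timepoint=timepoint,
        longest_diameter_mm=2.0 * semi_major * pixel_spacing_mm,
        is_primary=is_primary,
    )


def gen_followup(
    baseline: LesionImage,
    shrink_factor: float,
    sd_multiplier: float,
    seed: int = 0,
) -> LesionImage:
    """Treatment-effect transform of a baseline lesion.

    The lesion (image and mask) is geometrically scaled about the grid centre
    so the longest diameter becomes baseline x shrink_factor (whole pixels,
    floor 2 px); ROI intensities are rescaled to sd_multiplier x the baseline
    ROI SD around the baseline ROI mean; a small fresh acquisition-noise term
    (2% of the target SD) seeded by ``seed`` emulates the re-scan.
    """
    if shrink_factor <= 0:
        raise ValueError("shrink_factor must be positive")
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")

    spacing = baseline.pixel_spacing_mm
    diam_px = baseline.longest_diameter_mm / spacing
    new_diam_px = max(2, int(round(diam_px * shrink_factor)))
    f = new_diam_px / diam_px

    extent = baseline.pixels.shape[0]
    c = (extent - 1) / 2.0
    # output -> input mapping: input = (output - c)/f + c
    matrix = np.array([[1.0 / f, 0.0], [0.0, 1.0 / f]])
    offset = c - c / f
    zoomed = ndimage.affine_transform(
        baseline.pixels.astype(np.float64), matrix, offset=offset, order=1, mode="mirror"
    )
    mask = (
        ndimage.affine_transform(
            baseline.mask.astype(np.float64), matrix, offset=offset, order=0, mode="constant"
        )
        > 0.5
    )

    base_roi = baseline.pixels[baseline.mask].astype(np.float64)
    target_mean = base_roi.mean()
    target_sd = base_roi.std(ddof=0) * sd_multiplier
    roi = zoomed[mask]
    pixels = target_mean + (zoomed - roi.mean()) * (target_sd / roi.std(ddof=0))
    rng = np.random.default_rng(seed)
    pixels = pixels + rng.standard_normal(pixels.shape) * (0.02 * target_sd)

    return LesionImage(
        pixels=pixels.astype(np.float32),
        mask=mask,
        pixel_spacing_mm=spacing,
        patient_id=baseline.patient_id,
        lesion_id=baseline.lesion_id,
        organ=baseline.organ,
        timepoint=FOLLOWUP,
        longest_diameter_mm=new_diam_px * spacing,
        is_primary=baseline.is_primary,
    )


def _raw_roi_nsd(image: LesionImage) -> float:
    roi = image.pixels[image.mask].astype(np.float64)
    return nsd(float(roi.std(ddof=0)), roi.size)


def gen_cohort(
    config: SimulationConfig, with_images: bool = True
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a full cohort: lesions at both timepoints plus outcomes.

    The latent biomarker driving the hazard is the patient's mean baseline
    nSD computed on the raw ROI pixels: h = baseline_rate *
    exp(beta_nsd * nSD + beta_imdc * imdc_level).  OS and PFS event times are
    independent exponential draws from that hazard with PFS forced <= OS,
    both administratively censored at ``censor_days``.

    With ``with_images=False`` no pixel arrays are created: the latent nSD is
    computed from the sampled SD target and the analytic ellipse pixel count.
    This keeps the survival mechanism identical while making large replicate
    studies cheap; such records carry no lesions.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lesions_per_patient
    records: list[PatientRecord] = []
    truth_rows = []

    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        level = int(rng.choice(3, p=config.imdc_probs))
        n_lesions = int(rng.integers(lo, hi + 1))
        lesions: list[LesionImage] = []
        nsd_base_vals, nsd_fu_vals = [], []

        for j in range(n_lesions):
            organ = ORGAN_POOL[int(rng.integers(len(ORGAN_POOL)))]
            diam = float(rng.uniform(*config.diameter_range_mm))
            sd_t = float(rng.uniform(*config.sd_target_range))
            corr = float(rng.uniform(*config.correlation_length_range))
            aspect = float(rng.uniform(0.6, 1.0))
            shrink = float(rng.uniform(*config.shrink_factor_range))
            sd_mult = float(rng.uniform(*config.sd_multiplier_range))
            seed_img = int(rng.integers(2**31))
            seed_fu = int(rng.integers(2**31))

            if with_images:
                extent = max(config.image_extent, int(math.ceil(diam / config.pixel_spacing_mm)) + 4)
                base = gen_lesion_image(
                    extent,
                    config.mean_hu,
                    sd_t,
                    corr,
                    seed_img,
                    pixel_spacing_mm=config.pixel_spacing_mm,
                    aspect=aspect,
                    patient_id=pid,
                    lesion_id=f"L{j:02d}",
                    organ=organ,
                )
                fu = gen_followup(base, shrink, sd_mult, seed=seed_fu)
                lesions += [base, fu]
                nsd_base_vals.append(_raw_roi_nsd(base))
                nsd_fu_vals.append(_raw_roi_nsd(fu))
            else:
                a = diam / (2.0 * config.pixel_spacing_mm)
                n_base = max(2, int(round(math.pi * a * a * aspect)))
                n_fu = max(2, int(round(n_base * shrink * shrink)))
                nsd_base_vals.append(nsd(sd_t, n_base))
                nsd_fu_vals.append(nsd(sd_t * sd_mult, n_fu))

        nsd_base = float(np.mean(nsd_base_vals))
        nsd_fu = float(np.mean(nsd_fu_vals))
        hazard = config.baseline_rate * math.exp(
            config.beta_nsd * nsd_base + config.beta_imdc * level
        )
        t_os = float(rng.exponential(1.0 / hazard))
        t_pfs = min(float(rng.exponential(1.0 / hazard)), t_os)
        C = config.censor_days
        os_days, os_event = min(t_os, C), int(t_os <= C)
        pfs_days, pfs_event = min(t_pfs, C), int(t_pfs <= C)

        records.append(
            PatientRecord(
                patient_id=pid,
                imdc_group=IMDC_GROUPS[level],
                lesions=lesions,
                os_days=os_days,
                os_event=os_event,
                pfs_days=pfs_days,
                pfs_event=pfs_event,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "imdc_level": level,
                "nsd_baseline": nsd_base,
                "nsd_followup": nsd_fu,
                "os_days": os_days,
                "os_event": os_event,
                "pfs_days": pfs_days,
                "pfs_event": pfs_event,
            }
        )

    truth = GroundTruth(
        beta_nsd=config.beta_nsd,
        beta_imdc=config.beta_imdc,
        baseline_rate=config.baseline_rate,
        censor_days=config.censor_days,
        seed=config.seed,
        patients=pd.DataFrame(truth_rows),
    )
    return records, truth


def demo_config(n_patients: int = 60, seed: int = 0) -> SimulationConfig:
    """Quickstart cohort: defaults at a size that runs end to end in minutes."""
    return SimulationConfig(n_patients=n_patients, seed=seed)
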