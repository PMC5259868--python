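"""Core data containers shared across the pipeline."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASELINE = "baseline"
FOLLOWUP = "followup"
TIMEPOINTS = (BASELINE, FOLLOWUP)

#: ordinal encoding of the IMDC prognostic groups used throughout.
IMDC_LEVELS = {"good": 0, "intermediate": 1, "poor": 2}
IMDC_GROUPS = tuple(IMDC_LEVELS)


@dataclass
class LesionImage:
    """One 2D axial CT slice of a lesion with its ROI mask.

    Pixel values are in Hounsfield units; the mask delineates the lesion on
    the slice through its largest diameter.
    """

    pixels: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: float
    patient_id: str
    lesion_id: str
    organ: str
    timepoint: str
    longest_diameter_mm: float
    is_primary: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D slice")
        if self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must equal pixel shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one pixel")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.longest_diameter_mm <= 0:
            raise ValueError("longest_diameter_mm must be positive")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")

    @property
    def n_roi_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TextureFeatures:
    """First-order histogram statistics of filtered ROI values.

    ``nsd`` is the size-normalized standard deviation ln(SD)/ln(N) where N is
    the ROI pixel count; features that are undefined for the input (e.g. mpp
    with no positive pixels, nsd with SD <= 0) are NaN.
    """

    mpp: float
    sd: float
    skewness: float
    kurtosis: float
    entropy_bits: float
    nsd: float
    n_pixels: int

    FEATURE_NAMES = ("mpp", "sd", "skewness", "kurtosis", "entropy_bits", "nsd")

    def as_dict(self) -> dict:
        return {
            "mpp": self.mpp,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "entropy_bits": self.entropy_bits,
            "nsd": self.nsd,
            "n_pixels": self.n_pixels,
        }


@dataclass
class PatientRecord:
    """A patient's lesions at both timepoints plus clinical outcomes."""

    patient_id: str
    imdc_group: str
    lesions: list = field(default_factory=list)
    os_days: float = float("nan")
    os_event: int = 0
    pfs_days: float = float("nan")
    pfs_event: int = 0

    def __post_init__(self) -> None:
        if self.imdc_group not in IMDC_LEVELS:
            raise ValueError(f"imdc_group must be one of {IMDC_GROUPS}")
        for t in (self.os_days, self.pfs_days):
            if not math.isnan(t) and t < 0:
                raise ValueError("survival times must be non-negative")

    @property
    def imdc_level(self) -> int:
        return IMDC_LEVELS[self.imdc_group]

    def lesions_at(self, timepoint: str) -> list:
        return [l for l in self.lesions if l.timepoint == timepoint]
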