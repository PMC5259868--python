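"""Filtration-histogram texture analysis of CT lesion ROIs.

The technique has two stages: a band-pass Laplacian-of-Gaussian (LoG) filter
applied to the full image at a chosen spatial scale, followed by first-order
histogram statistics of the filtered values inside the (refined) ROI.  The
statistics are mean positive pixel intensity (MPP), standard deviation (SD),
skewness, excess kurtosis, histogram entropy, and the size-normalized
standard deviation

    nSD = ln(SD) / ln(N)

with N the number of ROI pixels, which corrects the dependence of the SD
estimate on lesion size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import LesionImage, TextureFeatures

# HU window used to drop air, streak artifacts and dense calcifications from
# the ROI before computing statistics.  Configurable everywhere they appear.
DEFAULT_HU_LOW = -50.0
DEFAULT_HU_HIGH = 300.0
DEFAULT_N_BINS = 128


class UnusableROIError(ValueError):
    """Raised when HU refinement leaves no usable ROI pixels."""


@dataclass(frozen=True)
class FilterSpec:
    """Spatial scale of the band-pass filter, in millimetres.

    Presets follow the fine/medium/coarse convention (2/4/6 mm).  The scale
    maps to the LoG Gaussian width as sigma_px = ssf_mm / (2 * pixel_spacing).
    """

    ssf_mm: float = 4.0

    FINE = 2.0
    MEDIUM = 4.0
    COARSE = 6.0

    def __post_init__(self) -> None:
        if not 2.0 <= self.ssf_mm <= 6.0:
            raise ValueError("ssf_mm must lie in [2, 6] mm")

    def sigma_pixels(self, pixel_spacing_mm: float) -> float:
        return self.ssf_mm / (2.0 * pixel_spacing_mm)


def nsd(sd: float, n: int) -> float:
    """Size-normalized standard deviation ln(SD)/ln(N).

    Undefined (NaN) when N < 2 (denominator ln N <= 0) or SD <= 0; these are
    missing features, not errors.
    """
    if n < 2 or sd <= 0 or math.isnan(sd):
        return float("nan")
    return math.log(sd) / math.log(n)


def refine_mask(
    image: LesionImage,
    hu_low: float = DEFAULT_HU_LOW,
    hu_high: float = DEFAULT_HU_HIGH,
) -> np.ndarray:
    """Drop ROI pixels outside [hu_low, hu_high] HU.

    Excludes air, streak artifacts and dense calcifications from the region
    of interest.  Raises :class:`UnusableROIError` if nothing survives.
    """
    if hu_low >= hu_high:
        raise ValueError("hu_low must be below hu_high")
    refined = image.mask & (image.pixels >= hu_low) & (image.pixels <= hu_high)
    if not refined.any():
        raise UnusableROIError(
            f"lesion {image.lesion_id}: no ROI pixels in [{hu_low}, {hu_high}] HU"
        )
    return refined


def log_kernel(sigma: float) -> np.ndarray:
    """Discrete negative-LoG kernel, truncated at 4*sigma, exactly zero-sum.

    The negative sign makes bright blobs of width ~sigma respond positively.
    The kernel is amplitude-normalized so its positive lobe sums to 1, which
    keeps filtered output on the Hounsfield scale of the input (a blob
    matching the filter scale maps to roughly its own contrast); the mean of
    the truncated kernel is then subtracted so the coefficients sum to
    exactly zero and constant images are annihilated.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(math.ceil(4.0 * sigma))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)
    r2 = x * x + y * y
    s2 = sigma * sigma
    kernel = (1.0 - r2 / (2.0 * s2)) * np.exp(-r2 / (2.0 * s2))
    kernel /= kernel[kernel > 0].sum()
    kernel -= kernel.mean()
    return kernel


def log_filter(image: LesionImage, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass filter the full image with a negative LoG at the given scale.

    The whole slice is convolved (mirror padding at borders); masking happens
    only afterwards so ROI-edge ringing does not contaminate the statistics.
    """
    sigma = spec.sigma_pixels(image.pixel_spacing_mm)
    if sigma < 0.5:
        raise ValueError(
            f"filter scale {spec.ssf_mm} mm is narrower than a pixel "
            f"(sigma = {sigma:.3f} px)"
        )
    if min(image.pixels.shape) < 4 * sigma:
        raise ValueError("image smaller than 4 sigma; cannot filter")
    kernel = log_kernel(sigma)
    return ndimage.convolve(image.pixels.astype(np.float64), kernel, mode="mirror")


def histogram_features(values, n_bins: int = DEFAULT_N_BINS) -> TextureFeatures:
    """First-order histogram statistics of (filtered) ROI values.

    SD is the population standard deviation (divisor N); kurtosis is excess
    (normal = 0); entropy is Shannon entropy in bits over ``n_bins``
    equal-width bins spanning the value range, 0 for a single-valued input.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("histogram_features requires at least one value")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    n = v.size
    mean = v.mean()
    sd = float(v.std(ddof=0))

    positive = v[v > 0]
    mpp = float(positive.mean()) if positive.size else float("nan")

    if sd > 0:
        z = (v - mean) / sd
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4) - 3.0)
    else:
        skewness = float("nan")
        kurtosis = float("nan")

    if v.max() == v.min():
        entropy_bits = 0.0
    else:
        counts, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
        p = counts[counts > 0] / n
        entropy_bits = float(-(p * np.log2(p)).sum())

    return TextureFeatures(
        mpp=mpp,
        sd=sd,
        skewness=skewness,
        kurtosis=kurtosis,
        entropy_bits=entropy_bits,
        nsd=nsd(sd, n),
        n_pixels=int(n),
    )


def extract_features(
    image: LesionImage,
    spec: FilterSpec = FilterSpec(),
    hu_low: float = DEFAULT_HU_LOW,
    hu_high: float = DEFAULT_HU_HIGH,
    n_bins: int = DEFAULT_N_BINS,
) -> TextureFeatures:
    """Full filtration-histogram pipeline for one lesion ROI.

    Composition refine_mask -> log_filter -> histogram_features.  N in the
    nSD formula is the refined-mask pixel count.
    """
    refined = refine_mask(image, hu_low=hu_low, hu_high=hu_high)
    filtered = log_filter(image, spec)
    return histogram_features(filtered[refined], n_bins=n_bins)
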