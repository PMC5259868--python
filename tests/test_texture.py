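"""Filtration-histogram texture computation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from texsurv.texture import (
    FilterSpec,
    UnusableROIError,
    extract_features,
    histogram_features,
    log_filter,
    log_kernel,
    nsd,
    refine_mask,
)
from texsurv.types import BASELINE, LesionImage
from texsurv.synthetic import gen_lesion_image

from _oracles import histogram_features_oracle


def _image(pixels, mask=None, spacing=0.933):
    pixels = np.asarray(pixels, dtype=np.float32)
    if mask is None:
        mask = np.ones_like(pixels, dtype=bool)
    return LesionImage(
        pixels=pixels, mask=mask, pixel_spacing_mm=spacing,
        patient_id="P000", lesion_id="L00", organ="liver",
        timepoint=BASELINE, longest_diameter_mm=20.0,
    )


# ---------------------------------------------------------------- nSD


@pytest.mark.parametrize(
    "sd, n, expected",
    [(100.0, 10000, 0.5), (1.0, 57, 0.0), (7.0, 7, 1.0), (12.0, 12, 1.0)],
)
def test_nsd_analytic_values(sd, n, expected):
    assert nsd(sd, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("sd, n", [(0.0, 100), (-3.0, 100), (5.0, 1), (5.0, 0)])
def test_nsd_undefined_inputs_are_missing(sd, n):
    assert np.isnan(nsd(sd, n))


def test_nsd_monotonicity():
    sds = np.linspace(1.5, 80, 40)
    vals = [nsd(s, 500) for s in sds]
    assert np.all(np.diff(vals) > 0), "nsd must increase with sd at fixed n"
    ns = np.arange(10, 500, 7)
    vals = [nsd(20.0, n) for n in ns]
    assert np.all(np.diff(vals) < 0), "nsd must decrease with n at fixed sd > 1"


# ---------------------------------------------------------------- refine_mask


def test_refine_mask_rules():
    pixels = np.full((16, 16), 50.0, dtype=np.float32)
    pixels[0, :2] = -500.0     # air
    pixels[1, :2] = 800.0      # calcification
    img = _image(pixels)
    refined = refine_mask(img, hu_low=-50, hu_high=300)
    assert refined.sum() == 16 * 16 - 4
    assert not refined[0, 0] and not refined[1, 0]
    # all in-range: identity
    assert refine_mask(_image(np.full((16, 16), 50.0))).sum() == 256


def test_refine_mask_empty_is_unusable():
    img = _image(np.full((16, 16), -900.0))
    with pytest.raises(UnusableROIError):
        refine_mask(img, hu_low=-50, hu_high=300)


def test_refine_mask_rejects_inverted_window():
    with pytest.raises(ValueError):
        refine_mask(_image(np.zeros((16, 16))), hu_low=300, hu_high=-50)


# ---------------------------------------------------------------- LoG filter


def test_constant_image_is_annihilated():
    img = _image(np.full((32, 32), 137.0))
    assert np.abs(log_filter(img)).max() < 1e-9


def test_impulse_response_is_the_kernel_and_zero_sum():
    sigma = FilterSpec().sigma_pixels(0.933)
    kernel = log_kernel(sigma)
    assert abs(kernel.sum()) < 1e-12
    extent = 64
    pixels = np.zeros((extent, extent), dtype=np.float32)
    pixels[extent // 2, extent // 2] = 1.0
    out = log_filter(_image(pixels))
    r = kernel.shape[0] // 2
    c = extent // 2
    patch = out[c - r : c + r + 1, c - r : c + r + 1]
    np.testing.assert_allclose(patch, kernel, atol=1e-12)
    assert abs(out.sum()) < 1e-9


def test_bandpass_prefers_matched_wavelength():
    """A grating at the filter's own scale responds much more strongly than a
    20x coarser one; checked against a dense sliding-window convolution."""
    spec = FilterSpec()
    sigma = spec.sigma_pixels(0.933)
    x = np.arange(64, dtype=np.float64)
    responses = {}
    for factor in (1.0, 20.0):
        wavelength = 2 * np.pi * sigma * factor
        grating = np.tile(np.sin(2 * np.pi * x / wavelength), (64, 1))
        img = _image(grating)
        out = log_filter(img, spec)
        # independent dense-convolution oracle
        kernel = log_kernel(sigma)
        r = kernel.shape[0] // 2
        padded = np.pad(grating, r, mode="reflect")
        windows = np.lib.stride_tricks.sliding_window_view(padded, kernel.shape)
        oracle = np.einsum("ijkl,kl->ij", windows, kernel)
        np.testing.assert_allclose(out, oracle, atol=1e-8)
        responses[factor] = out.std()
    assert responses[1.0] > 10 * responses[20.0]


def test_filter_scale_narrower_than_pixel_rejected():
    img = _image(np.zeros((32, 32)), spacing=2.5)  # sigma = 4/(2*2.5) = 0.8
    log_filter(img)  # fine
    with pytest.raises(ValueError):
        log_filter(_image(np.zeros((32, 32)), spacing=4.5))  # sigma 0.44 < 0.5


def test_filter_spec_presets_and_bounds():
    assert FilterSpec.FINE == 2.0 and FilterSpec.COARSE == 6.0
    with pytest.raises(ValueError):
        FilterSpec(ssf_mm=7.0)


# ---------------------------------------------------------------- histogram


def test_histogram_features_examples():
    f = histogram_features([-2.0, 3.0, 5.0])
    assert f.mpp == pytest.approx(4.0)

    const = histogram_features([7.0] * 10)
    assert const.sd == 0.0 and const.entropy_bits == 0.0
    assert np.isnan(const.skewness) and np.isnan(const.kurtosis)
    assert np.isnan(const.nsd)

    # 1000 values filling 8 bins equally -> entropy log2(8) = 3 bits
    vals = np.repeat(np.arange(8) + 0.5, 125) / 8.0
    assert histogram_features(vals, n_bins=8).entropy_bits == pytest.approx(3.0)


def test_histogram_features_empty_input():
    with pytest.raises(ValueError):
        histogram_features([])


def test_histogram_features_match_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        vals = rng.normal(rng.uniform(-10, 10), rng.uniform(0.5, 30), size=50)
        got = histogram_features(vals, n_bins=16).as_dict()
        want = histogram_features_oracle(vals, n_bins=16)
        for key, expected in want.items():
            assert got[key] == pytest.approx(expected, rel=1e-9, nan_ok=True), key


@given(st.lists(st.floats(-500, 500), min_size=2, max_size=200).filter(
    lambda v: len(set(v)) > 1))
@settings(max_examples=100, derandomize=True)
def test_entropy_bounds(values):
    f = histogram_features(values, n_bins=32)
    assert 0.0 <= f.entropy_bits <= np.log2(32) + 1e-12


# ---------------------------------------------------------------- composition


def test_feature_offset_invariance():
    img = gen_lesion_image(48, 60, 25, 1.0, seed=3)
    shifted = _image(img.pixels + 100.0, img.mask)
    a = extract_features(img, hu_low=-1e6, hu_high=1e6)
    b = extract_features(shifted, hu_low=-1e6, hu_high=1e6)
    for name in ("mpp", "sd", "skewness", "kurtosis", "entropy_bits", "nsd"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-6), name


def test_feature_rotation_invariance():
    img = gen_lesion_image(48, 60, 25, 1.0, seed=4)
    rot = _image(np.rot90(img.pixels).copy(), np.rot90(img.mask).copy())
    a, b = extract_features(img), extract_features(rot)
    for name in ("mpp", "sd", "skewness", "kurtosis", "entropy_bits", "nsd"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-6), name


def test_heterogeneity_orders_sd_and_nsd():
    hi = extract_features(gen_lesion_image(64, 60, 40, 1.5, seed=5, aspect=0.8))
    lo = extract_features(gen_lesion_image(64, 60, 10, 1.5, seed=5, aspect=0.8))
    assert hi.sd > lo.sd and hi.nsd > lo.nsd


def test_extract_is_deterministic():
    img = gen_lesion_image(48, 60, 25, 1.0, seed=6)
    a, b = extract_features(img), extract_features(img)
    assert a == b


def test_fully_out_of_range_roi_errors():
    img = _image(np.full((32, 32), 900.0))
    with pytest.raises(UnusableROIError):
        extract_features(img)
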