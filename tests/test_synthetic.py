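"""Synthetic cohort generator: images, treatment transform, survival mechanism."""
import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from texsurv.io import read_cohort, write_cohort
from texsurv.synthetic import (
    SimulationConfig,
    gen_cohort,
    gen_followup,
    gen_lesion_image,
)
from texsurv.types import FOLLOWUP


# ---------------------------------------------------------------- lesion images


def test_roi_hits_mean_and_sd_targets():
    img = gen_lesion_image(64, 60.0, 20.0, 0.0, seed=11)
    roi = img.pixels[img.mask]
    assert roi.size >= 1000
    assert 19.0 <= roi.std() <= 21.0
    assert abs(roi.mean() - 60.0) <= 0.02 * 60.0


def test_vanishing_noise_limit():
    img = gen_lesion_image(64, 60.0, 1e-6, 1.0, seed=12)
    roi = img.pixels[img.mask]
    assert np.abs(roi - 60.0).max() < 1e-4


def test_same_seed_bit_identical():
    a = gen_lesion_image(48, 60.0, 25.0, 1.5, seed=13)
    b = gen_lesion_image(48, 60.0, 25.0, 1.5, seed=13)
    assert np.array_equal(a.pixels, b.pixels) and np.array_equal(a.mask, b.mask)


@pytest.mark.parametrize("kwargs", [
    dict(extent=8, mean_hu=60, sd_target=10, corr_len=1),
    dict(extent=32, mean_hu=60, sd_target=0.0, corr_len=1),
    dict(extent=32, mean_hu=60, sd_target=10, corr_len=-1),
])
def test_invalid_lesion_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        gen_lesion_image(seed=0, **kwargs)


# ---------------------------------------------------------------- follow-up


def test_followup_identity_transform():
    base = gen_lesion_image(48, 60.0, 25.0, 1.0, seed=14)
    fu = gen_followup(base, shrink_factor=1.0, sd_multiplier=1.0, seed=1)
    assert fu.longest_diameter_mm == pytest.approx(base.longest_diameter_mm)
    assert fu.timepoint == FOLLOWUP
    base_sd = base.pixels[base.mask].std()
    assert fu.pixels[fu.mask].std() == pytest.approx(base_sd, rel=0.05)


def test_followup_shrinks_diameter():
    base = gen_lesion_image(48, 60.0, 25.0, 1.0, seed=15, pixel_spacing_mm=1.0)
    # ~30 mm lesion at 1 mm spacing
    assert base.longest_diameter_mm == pytest.approx(2 * (48 / 2 - 1), abs=1e-9)
    fu = gen_followup(base, shrink_factor=0.67, sd_multiplier=1.0, seed=1)
    assert abs(fu.longest_diameter_mm - 0.67 * base.longest_diameter_mm) <= 1.0


def test_followup_rescales_sd():
    base = gen_lesion_image(48, 60.0, 25.0, 1.0, seed=16)
    fu = gen_followup(base, shrink_factor=1.0, sd_multiplier=2.0, seed=1)
    ratio = fu.pixels[fu.mask].std() / base.pixels[base.mask].std()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_followup_diameter_floor_and_precondition():
    base = gen_lesion_image(48, 60.0, 25.0, 1.0, seed=17)
    tiny = gen_followup(base, shrink_factor=0.01, sd_multiplier=1.0, seed=1)
    assert tiny.longest_diameter_mm >= 2 * base.pixel_spacing_mm - 1e-9
    with pytest.raises(ValueError):
        gen_followup(base, shrink_factor=0.0, sd_multiplier=1.0)


# ---------------------------------------------------------------- cohorts


def _null_config(**kw):
    defaults = dict(n_patients=500, beta_nsd=0.0, beta_imdc=0.0,
                    baseline_rate=0.0074, seed=100)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_null_cohort_km_median_matches_exponential():
    """With both betas 0 times are exponential(r): KM median ~= ln2/r."""
    records, _ = gen_cohort(_null_config(), with_images=False)
    kmf = KaplanMeierFitter()
    kmf.fit([r.os_days for r in records], [r.os_event for r in records])
    expected = math.log(2) / 0.0074
    assert kmf.median_survival_time_ == pytest.approx(expected, rel=0.10)


def test_null_cohort_censoring_fraction():
    """Censoring fraction at horizon C is exp(-rC) within 3 binomial SEs."""
    C, r, n = 100.0, 0.0074, 500
    records, _ = gen_cohort(_null_config(censor_days=C), with_images=False)
    frac = np.mean([1 - rec.os_event for rec in records])
    p = math.exp(-r * C)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * se


def test_zero_censor_horizon_censors_everyone():
    records, _ = gen_cohort(_null_config(n_patients=20, censor_days=0.0),
                            with_images=False)
    assert all(rec.os_days == 0.0 and rec.os_event == 0 for rec in records)
    assert all(rec.pfs_days == 0.0 and rec.pfs_event == 0 for rec in records)


def test_protective_nsd_orders_survival():
    """Strongly negative beta_nsd: high-nSD patients live longer on average."""
    records, truth = gen_cohort(
        SimulationConfig(n_patients=500, beta_nsd=-5.0, beta_imdc=0.0, seed=101),
        with_images=False,
    )
    df = truth.patients
    median = df["nsd_baseline"].median()
    top = df[df["nsd_baseline"] > median]["os_days"].mean()
    bottom = df[df["nsd_baseline"] <= median]["os_days"].mean()
    assert top > bottom


def test_cohort_determinism_and_structure():
    config = SimulationConfig(n_patients=4, seed=21)
    rec_a, truth_a = gen_cohort(config)
    rec_b, truth_b = gen_cohort(config)
    for a, b in zip(rec_a, rec_b):
        assert a.os_days == b.os_days and a.pfs_days == b.pfs_days
        for la, lb in zip(a.lesions, b.lesions):
            assert np.array_equal(la.pixels, lb.pixels)
    assert truth_a.patients.equals(truth_b.patients)
    # stored coefficients echo the generating config
    assert truth_a.beta_nsd == config.beta_nsd
    assert truth_a.beta_imdc == config.beta_imdc
    # PFS never exceeds OS, times non-negative
    for rec in rec_a:
        assert 0 <= rec.pfs_days <= rec.os_days


def test_roi_pixel_counts_span_order_of_magnitude(demo_cohort):
    _, records, _ = demo_cohort
    counts = [l.n_roi_pixels for r in records for l in r.lesions]
    assert max(counts) / min(counts) >= 10


@pytest.mark.parametrize("kw", [
    dict(n_patients=1),
    dict(imdc_probs=(0.5, 0.4, 0.2)),
    dict(sd_target_range=(0.0, 10.0)),
    dict(baseline_rate=0.0),
])
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        SimulationConfig(**kw)


# ---------------------------------------------------------------- round trip


def test_write_and_read_cohort_roundtrip(tmp_path):
    records, truth = gen_cohort(SimulationConfig(n_patients=2, seed=22))
    manifest = write_cohort(records, tmp_path)
    n_lesion_tp = sum(len(r.lesions) for r in records)
    assert len(manifest["images"]) == 2 * n_lesion_tp  # img + mask each

    back = read_cohort(tmp_path)
    assert len(back) == len(records)
    by_id = {r.patient_id: r for r in back}
    for rec in records:
        other = by_id[rec.patient_id]
        assert other.imdc_group == rec.imdc_group
        assert other.os_days == pytest.approx(rec.os_days)
        assert len(other.lesions) == len(rec.lesions)
        mine = {(l.lesion_id, l.timepoint): l for l in rec.lesions}
        for lesion in other.lesions:
            orig = mine[(lesion.lesion_id, lesion.timepoint)]
            np.testing.assert_array_equal(lesion.pixels, orig.pixels)
            np.testing.assert_array_equal(lesion.mask, orig.mask)
            assert lesion.pixel_spacing_mm == pytest.approx(orig.pixel_spacing_mm)


def test_write_empty_cohort_errors(tmp_path):
    with pytest.raises(ValueError):
        write_cohort([], tmp_path)
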