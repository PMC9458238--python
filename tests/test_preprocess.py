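"""Preprocessing stages: exact small cases, planted recovery, stage order."""

import numpy as np
import pandas as pd
import pytest

from msi_ith import (
    ComponentModel,
    MSIDataset,
    PreprocessParams,
    align_peaks,
    detect_outlier_pixels,
    estimate_abundance,
    fit_gmm_components,
    preprocess_pipeline,
    simulate_dataset,
    subtract_baseline,
    tic_normalize,
    unify_mass_channels,
)
from msi_ith.preprocess import (
    STAGE_ORDER,
    average_spectrum,
    estimate_pixel_shifts,
    merge_isotope_envelopes,
    subtract_baseline_dataset,
)

from conftest import tiny_config


def make_dataset(mz, spectra):
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    n = len(spectra)
    return MSIDataset(
        mz_axis=mz,
        spectra=spectra,
        coords=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]),
        roi_labels=np.zeros(n, dtype=int),
        roi_meta=pd.DataFrame(
            [{"patient_id": "P", "group": "NED", "tissue": "T",
              "lhr_category": "weak"}]
        ),
    )


def gaussian(mz, mu, sigma, area=1.0):
    return area * np.exp(-0.5 * ((mz - mu) / sigma) ** 2) / (
        sigma * np.sqrt(2 * np.pi)
    )


# ---------------------------------------------------------------------------
# mass channel unification
# ---------------------------------------------------------------------------


def test_unify_identity_on_equal_axes():
    mz = np.linspace(700, 710, 101)
    ds = make_dataset(mz, np.vstack([np.ones(101), np.arange(101.0)]))
    (out,) = unify_mass_channels([ds])
    assert np.array_equal(out.mz_axis, mz)
    assert np.array_equal(out.spectra, ds.spectra)


def test_unify_constant_spectrum_stays_constant():
    mz1 = np.linspace(700, 710, 101)
    mz2 = mz1 + 0.05  # half-channel offset
    ds1 = make_dataset(mz1, np.full((1, 101), 3.0))
    ds2 = make_dataset(mz2, np.full((1, 101), 5.0))
    out1, out2 = unify_mass_channels([ds1, ds2])
    assert np.allclose(out1.spectra, 3.0)
    assert np.allclose(out2.spectra, 5.0)
    assert np.array_equal(out1.mz_axis, out2.mz_axis)


def test_unify_linear_ramp_interpolated_exactly():
    # linear interpolation is exact on linear functions
    mz1 = np.linspace(700, 710, 101)
    mz2 = mz1 + 0.05
    ramp = 2.0 * mz2 - 1000.0
    ds1 = make_dataset(mz1, np.ones(101))
    ds2 = make_dataset(mz2, ramp)
    _, out2 = unify_mass_channels([ds1, ds2])
    inside = (out2.mz_axis >= mz2[0]) & (out2.mz_axis <= mz2[-1])
    assert np.allclose(
        out2.spectra[0][inside], 2.0 * out2.mz_axis[inside] - 1000.0
    )


def test_unify_disjoint_ranges_error():
    ds1 = make_dataset(np.linspace(700, 710, 50), np.ones(50))
    ds2 = make_dataset(np.linspace(800, 810, 50), np.ones(50))
    with pytest.raises(ValueError, match="disjoint"):
        unify_mass_channels([ds1, ds2])


# ---------------------------------------------------------------------------
# baseline subtraction
# ---------------------------------------------------------------------------


def test_baseline_removes_constant_offset():
    assert np.allclose(subtract_baseline(np.full(500, 7.0), 51), 0.0)


def test_baseline_preserves_isolated_peak_apex():
    mz = np.linspace(700, 720, 2001)
    spec = gaussian(mz, 710.0, 0.3)
    out = subtract_baseline(spec, 501)  # window >> peak width
    apex = spec.max()
    assert abs(out.max() - apex) <= 0.01 * apex


def test_baseline_residual_bounded_on_linear_ramp():
    mz = np.linspace(700, 720, 2001)
    slope_per_channel = 0.002
    ramp = slope_per_channel * np.arange(len(mz))
    spec = gaussian(mz, 710.0, 0.3) + ramp
    window = 301
    out = subtract_baseline(spec, window)
    off_peak = np.abs(mz - 710.0) > 3.0
    assert out[off_peak].max() <= slope_per_channel * window


def test_baseline_window_validation():
    with pytest.raises(ValueError):
        subtract_baseline(np.ones(10), 2)
    with pytest.raises(ValueError):
        subtract_baseline(np.ones(10), 11)


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------


def test_no_outliers_when_tics_identical():
    mz = np.linspace(700, 710, 64)
    ds = make_dataset(mz, np.tile(np.ones(64), (20, 1)))
    assert not detect_outlier_pixels(ds).any()


def test_single_extreme_pixel_flagged_exactly():
    mz = np.linspace(700, 710, 64)
    spectra = np.tile(np.linspace(1, 2, 64), (1000, 1))
    spectra[123] *= 100.0
    flags = detect_outlier_pixels(make_dataset(mz, spectra))
    assert flags.sum() == 1 and flags[123]


def test_outlier_recovery_on_synthetic_plant():
    cfg = tiny_config(outlier_fraction=0.02, roi_shape=(24, 24), seed=13)
    ds, gt = simulate_dataset(cfg)
    ds = subtract_baseline_dataset(ds, 101)
    flags = detect_outlier_pixels(ds)
    truth = gt.outlier_mask
    sensitivity = flags[truth].mean()
    false_rate = flags[~truth].mean()
    assert sensitivity >= 0.9
    assert false_rate <= 0.01


def test_outliers_require_ten_pixels():
    mz = np.linspace(700, 710, 16)
    with pytest.raises(ValueError):
        detect_outlier_pixels(make_dataset(mz, np.ones((5, 16))))


# ---------------------------------------------------------------------------
# peak alignment
# ---------------------------------------------------------------------------


def test_alignment_zero_shift_for_reference_pixel():
    mz = np.linspace(700, 720, 2001)
    ref = gaussian(mz, 710.0, 0.3)
    ds = make_dataset(mz, ref)
    assert estimate_pixel_shifts(ds, ref)[0] == 0


def test_alignment_recovers_constructed_shift():
    mz = np.linspace(700, 720, 2001)
    ref = gaussian(mz, 710.0, 0.3)
    shifted = np.roll(ref, 2)  # pixel = reference shifted +2 channels
    ds = make_dataset(mz, shifted)
    shifts = estimate_pixel_shifts(ds, ref)
    assert shifts[0] == -2
    aligned = align_peaks(ds, ref)
    inner = slice(5, -5)
    assert np.allclose(aligned.spectra[0][inner], ref[inner], atol=1e-12)


def test_alignment_recovers_random_jitter():
    rng = np.random.default_rng(7)
    mz = np.linspace(700, 760, 6001)
    ref = sum(gaussian(mz, m, 0.3) for m in np.arange(705.0, 756.0, 5.0))
    true_shifts = rng.integers(-3, 4, size=200)
    spectra = np.vstack([np.roll(ref, s) for s in true_shifts])
    ds = make_dataset(mz, spectra)
    est = estimate_pixel_shifts(ds, ref, max_shift=5)
    assert np.mean(est == -true_shifts) >= 0.95


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------


def test_tic_normalization_cases():
    mz = np.linspace(700, 710, 64)
    base = np.abs(np.sin(np.arange(64))) + 0.1
    ds = make_dataset(mz, np.vstack([base, 3.0 * base]))
    out = tic_normalize(ds)
    tics = out.tic()
    assert np.allclose(tics, tics[0], rtol=1e-9)  # all TICs equal
    # pixel with twice the mean TIC is halved: construct directly
    ds2 = make_dataset(mz, np.vstack([base, base, 4.0 * base]))
    out2 = tic_normalize(ds2)
    assert np.allclose(out2.spectra[2], 4.0 * base * (2.0 / 4.0))
    # all pixels equal TIC -> unchanged
    ds3 = make_dataset(mz, np.vstack([base, base[::-1]]))
    out3 = tic_normalize(ds3)
    assert np.allclose(out3.spectra, ds3.spectra)


def test_tic_zero_pixel_rejected():
    mz = np.linspace(700, 710, 64)
    ds = make_dataset(mz, np.vstack([np.ones(64), np.zeros(64)]))
    with pytest.raises(ValueError):
        tic_normalize(ds)


# ---------------------------------------------------------------------------
# GMM componentization
# ---------------------------------------------------------------------------


def test_gmm_single_gaussian_recovered():
    mz = np.linspace(995.0, 1005.0, 1001)
    spec = gaussian(mz, 1000.0, 0.3)
    model = fit_gmm_components(spec, mz)
    assert model.n_components == 1
    assert abs(model.means[0] - 1000.0) <= 0.05
    assert abs(model.sigmas[0] - 0.3) <= 0.05


def test_gmm_two_peaks_ten_sigma_apart():
    mz = np.linspace(990.0, 1010.0, 2001)
    dm = mz[1] - mz[0]
    spec = gaussian(mz, 998.0, 0.3) + 0.5 * gaussian(mz, 1001.0, 0.3)
    model = fit_gmm_components(spec, mz)
    assert model.n_components == 2
    assert abs(model.means[0] - 998.0) <= 0.5 * dm
    assert abs(model.means[1] - 1001.0) <= 0.5 * dm


def test_gmm_requires_maxima_above_threshold():
    mz = np.linspace(700, 710, 100)
    with pytest.raises(ValueError):
        fit_gmm_components(np.zeros(100), mz)


def test_gmm_many_peak_recovery_small_scale():
    # denser variant of the componentization check at unit-test size
    cfg = tiny_config(n_peaks=40, mz_max=1100.0, n_channels=4000,
                      roi_shape=(8, 8), noise_sd=0.01, seed=21)
    ds, gt = simulate_dataset(cfg)
    ds = subtract_baseline_dataset(ds, 101)
    model = fit_gmm_components(average_spectrum(ds), ds.mz_axis, tol=1e-6)
    hit = sum(
        np.min(np.abs(model.means - mu)) <= 2 * s
        for mu, s in zip(gt.peak_means, gt.peak_sigmas)
    )
    assert hit >= 0.95 * len(gt.peak_means)


def test_isotope_envelope_merge_collapses_chain():
    model = ComponentModel(
        means=[1000.0, 1001.00235, 1002.0047, 1010.0],
        sigmas=[0.3, 0.3, 0.3, 0.3],
        weights=[0.4, 0.2, 0.1, 0.3],
    )
    merged = merge_isotope_envelopes(model)
    assert merged.n_components == 2
    np.testing.assert_allclose(merged.means, [1000.0, 1010.0])
    np.testing.assert_allclose(merged.weights, [0.7, 0.3])


# ---------------------------------------------------------------------------
# abundance estimation
# ---------------------------------------------------------------------------


def test_abundance_matches_closed_form_self_convolution():
    # integral of a squared unit-area Gaussian is 1 / (2 sigma sqrt(pi))
    mz = np.linspace(990.0, 1010.0, 4001)
    sigma, area = 0.3, 5.0
    model = ComponentModel(means=[1000.0], sigmas=[sigma], weights=[1.0])
    ds = make_dataset(mz, area * gaussian(mz, 1000.0, sigma))
    ab = estimate_abundance(ds, model)
    expected = area / (2.0 * sigma * np.sqrt(np.pi))
    assert ab.values[0, 0] == pytest.approx(expected, rel=1e-3)


def test_abundance_zero_spectrum_is_zero():
    mz = np.linspace(990.0, 1010.0, 1001)
    model = ComponentModel(means=[1000.0], sigmas=[0.3], weights=[1.0])
    ab = estimate_abundance(ds := make_dataset(mz, np.zeros(1001)), model)
    assert np.all(ab.values == 0)


def test_abundance_axis_mismatch_error():
    mz = np.linspace(990.0, 1010.0, 1001)
    model = ComponentModel(means=[2000.0], sigmas=[0.3], weights=[1.0])
    with pytest.raises(ValueError):
        estimate_abundance(make_dataset(mz, np.ones(1001)), model)


def test_abundance_recovers_planted_profiles_noise_free():
    cfg = tiny_config(noise_sd=0.0, tic_cv=0.0, baseline_amplitude=0.0,
                      outlier_fraction=0.0, roi_shape=(8, 8), seed=17,
                      peak_sigma_range=(0.25, 0.3))
    ds, gt = simulate_dataset(cfg)
    model = fit_gmm_components(average_spectrum(ds), ds.mz_axis, tol=1e-6)
    ab = estimate_abundance(ds, model)
    # map fitted components onto planted peaks
    pairs = [
        (i, int(np.argmin(np.abs(model.means - mu))))
        for i, mu in enumerate(gt.peak_means)
        if np.min(np.abs(model.means - mu)) <= 2 * gt.peak_sigmas[i]
    ]
    assert len(pairs) >= 0.9 * cfg.n_peaks
    mi = [p[0] for p in pairs]
    mj = [p[1] for p in pairs]
    for p in range(0, ds.n_pixels, 7):
        est = ab.values[p][mj]
        planted = gt.cluster_mean_profiles[gt.cluster_label_map[p]][mi]
        r = np.corrcoef(est, planted)[0, 1]
        assert r >= 0.99


# ---------------------------------------------------------------------------
# pipeline contracts
# ---------------------------------------------------------------------------


def test_pipeline_stage_order_contract(tiny_preprocessed):
    assert tuple(tiny_preprocessed.provenance) == STAGE_ORDER


def test_pipeline_idempotent_on_own_output(tiny_preprocessed):
    ds = tiny_preprocessed.dataset
    # baseline already flat (up to the clipped noise floor)
    again = subtract_baseline_dataset(ds, 101)
    rel_change = np.abs(again.spectra - ds.spectra).sum() / ds.spectra.sum()
    assert rel_change < 0.05
    assert np.abs(again.spectra - ds.spectra).max() < 0.01 * ds.spectra.max()
    # TICs already equal
    renorm = tic_normalize(ds)
    assert np.allclose(renorm.spectra, ds.spectra, rtol=1e-9)
    # shifts already zero
    shifts = estimate_pixel_shifts(ds, average_spectrum(ds))
    assert np.all(shifts == 0)


def test_pipeline_outputs_consistent(tiny_preprocessed):
    res = tiny_preprocessed
    assert res.abundances.n_pixels == res.dataset.n_pixels
    assert res.abundances.n_components == res.model.n_components
    assert np.all(res.abundances.values >= 0)
    assert np.all(np.diff(res.model.means) >= 0)
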