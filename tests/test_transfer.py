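"""Spectral averaging, SNR estimation, Wiener regularization, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m2mcalib import (
    CoverageError,
    DegenerateInputError,
    DepthSpectra,
    M2MCalibrator,
    SNRProfile,
    TransferFunction,
    apply_transfer,
    average_power_spectra,
    build_bidirectional,
    estimate_snr_profile,
    estimate_transfer_magnitude,
    wiener_regularize,
)

N_FFT = 200
FS = 40e6


def make_spectra(power):
    power = np.atleast_2d(np.asarray(power, dtype=float))
    nz, nb = power.shape
    return DepthSpectra(
        power=power,
        freq_grid=np.linspace(0, FS / 2, nb),
        n_source_patches_per_zone=np.full(nz, 10),
    )


def tf_with_gain(gain, direction="train_to_test"):
    gain = np.atleast_2d(np.asarray(gain, dtype=float))
    freq = np.fft.rfftfreq(N_FFT, d=1 / FS)
    assert gain.shape[1] == freq.size
    return TransferFunction(gamma_raw=gain, gamma_wiener=gain, freq_grid=freq,
                            direction=direction)


class TestAveragePowerSpectra:
    def test_impulse_gives_flat_spectrum(self):
        X = np.zeros((3, N_FFT, 4), dtype=np.float32)
        X[:, 0, :] = 1.0
        spec = average_power_spectra(X, n_zones=1, zones=np.zeros(3, int))
        np.testing.assert_allclose(spec.power[0], 1.0 / N_FFT)

    def test_tone_concentrates_at_its_bin(self):
        t = np.arange(N_FFT) / FS
        col = np.cos(2 * np.pi * 5e6 * t)
        X = np.tile(col[None, :, None], (2, 1, 4)).astype(np.float32)
        spec = average_power_spectra(X, n_zones=1, zones=np.zeros(2, int))
        assert spec.freq_grid[np.argmax(spec.power[0])] == pytest.approx(5e6)

    def test_white_noise_level_matches_welch_oracle(self, rng):
        # E[|X_k|^2 / N] = sigma^2 for white noise; Monte-Carlo at 1e4 columns
        sigma = 1.7
        n_cols = 10_000
        X = rng.normal(0, sigma, size=(n_cols // 20, N_FFT, 20))
        spec = average_power_spectra(X, n_zones=1, zones=np.zeros(X.shape[0], int))
        interior = spec.power[0][1:-1]
        assert interior.mean() == pytest.approx(sigma**2, rel=0.02)

    def test_missing_zone_is_coverage_error(self, rng):
        X = rng.normal(size=(4, N_FFT, 3))
        with pytest.raises(CoverageError, match=r"\[1\]"):
            average_power_spectra(X, n_zones=2, zones=np.zeros(4, int))


class TestSNR:
    def test_direct_evaluation(self):
        snr = estimate_snr_profile(make_spectra([4.0, 2.0, 8.0]), make_spectra([4.0, 2.0, 8.0]))
        np.testing.assert_allclose(snr.snr_train[0], [1.0, 0.0, 3.0])
        np.testing.assert_allclose(snr.snr, snr.snr_train)

    def test_elementwise_minimum(self):
        a = make_spectra([2.0, 1.0, 4.0])  # snr [1, 0, 3]
        b = make_spectra([1.0, 6.0, 3.0])  # snr [0, 5, 2]
        snr = estimate_snr_profile(a, b)
        np.testing.assert_allclose(snr.snr[0], [0.0, 0.0, 2.0])

    def test_floor_bin_has_zero_snr(self, rng):
        p = rng.uniform(1.0, 5.0, size=(3, 20))
        snr = estimate_snr_profile(make_spectra(p), make_spectra(p))
        assert np.all(snr.snr.min(axis=1) == 0.0)

    def test_zero_floor_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_snr_profile(make_spectra([0.0, 1.0]), make_spectra([1.0, 2.0]))


class TestTransferMagnitude:
    def test_identical_spectra_give_unity(self, rng):
        p = rng.uniform(0.5, 2.0, size=(2, 30))
        tf = estimate_transfer_magnitude(make_spectra(p), make_spectra(p))
        np.testing.assert_allclose(tf.gamma_raw, 1.0)

    def test_amplitude_scaling_homogeneity(self, rng):
        p = rng.uniform(0.5, 2.0, size=(2, 30))
        c = 3.0
        tf = estimate_transfer_magnitude(make_spectra(p), make_spectra(c**2 * p))
        np.testing.assert_allclose(tf.gamma_raw, c)

    def test_directions_are_reciprocal(self, rng):
        pa = rng.uniform(0.5, 2.0, size=(2, 30))
        pb = rng.uniform(0.5, 2.0, size=(2, 30))
        fwd = estimate_transfer_magnitude(make_spectra(pa), make_spectra(pb), "train_to_test")
        bwd = estimate_transfer_magnitude(make_spectra(pa), make_spectra(pb), "test_to_train")
        np.testing.assert_allclose(fwd.gamma_raw * bwd.gamma_raw, 1.0, rtol=1e-10)


class TestWiener:
    @pytest.mark.parametrize(
        "gamma,snr,expected",
        [
            (1.0, np.inf, 1.0),  # high SNR leaves the gain unchanged
            (2.0, 1.0, 0.4),  # |G|^-1 / (|G|^-2 + SNR^-1) = 0.4
            (1.5, 0.0, 0.0),  # zero SNR denoises to zero
            (0.0, 5.0, 0.0),  # zero raw gain stays zero
        ],
    )
    def test_closed_form_values(self, gamma, snr, expected):
        tf = TransferFunction(
            gamma_raw=np.array([[gamma]]), freq_grid=np.array([0.0]), direction="train_to_test"
        )
        prof = SNRProfile(*(np.array([[snr]]),) * 3, np.array([1.0]), np.array([1.0]))
        out = wiener_regularize(tf, prof)
        assert out.gamma_wiener[0, 0] == pytest.approx(expected)

    def test_monotone_in_snr_from_zero_to_gamma(self):
        snr_grid = np.concatenate([[0.0], np.logspace(-3, 6, 200)])
        for gamma in (0.25, 1.0, 3.0):
            tf = TransferFunction(
                gamma_raw=np.full((1, snr_grid.size), gamma),
                freq_grid=np.linspace(0, 1, snr_grid.size),
                direction="train_to_test",
            )
            prof = SNRProfile(*(snr_grid[None, :],) * 3, np.array([1.0]), np.array([1.0]))
            gw = wiener_regularize(tf, prof).gamma_wiener[0]
            assert np.all(np.diff(gw) >= -1e-12)
            assert gw[0] == 0.0
            assert gw[-1] == pytest.approx(gamma, rel=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(gamma=st.floats(0.1, 10.0), snr=st.floats(0.0, 1e6))
    def test_bidirectional_product_bounded_by_one(self, gamma, snr):
        # regularized forward x backward gains never exceed unity
        def wiener(g, s):
            return g * s / (s + g**2) if s > 0 else 0.0

        prod = wiener(gamma, snr) * wiener(1.0 / gamma, snr)
        assert prod <= 1.0 + 1e-12

    def test_negative_snr_rejected(self):
        tf = TransferFunction(np.ones((1, 2)), np.array([0.0, 1.0]), "train_to_test")
        prof = SNRProfile(*(np.array([[-1.0, 1.0]]),) * 3, np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            wiener_regularize(tf, prof)


class TestApplyTransfer:
    def test_unit_gain_is_identity(self, rng):
        X = rng.normal(size=(6, N_FFT, 5)).astype(np.float32)
        zones = np.zeros(6, int)
        out = apply_transfer(X, tf_with_gain(np.ones(N_FFT // 2 + 1)), zones=zones)
        np.testing.assert_allclose(out, X, atol=1e-5)

    def test_spectral_shaping_of_white_noise(self, rng):
        gain = 1.0 + 0.8 * np.sin(np.linspace(0, np.pi, N_FFT // 2 + 1))
        X = rng.normal(size=(400, N_FFT, 26)).astype(np.float32)
        zones = np.zeros(400, int)
        out = apply_transfer(X, tf_with_gain(gain), zones=zones)
        p_out = average_power_spectra(out, n_zones=1, zones=zones).power[0]
        p_in = average_power_spectra(X, n_zones=1, zones=zones).power[0]
        np.testing.assert_allclose(p_out[1:-1] / p_in[1:-1], gain[1:-1] ** 2, rtol=0.05)

    def test_zone_out_of_range_rejected(self, rng):
        X = rng.normal(size=(2, N_FFT, 3)).astype(np.float32)
        tf = tf_with_gain(np.ones(N_FFT // 2 + 1))
        with pytest.raises(ValueError, match="zones"):
            apply_transfer(X, tf, zones=np.array([0, 5]))

    def test_fir_mode_approximates_fft_mode(self, rng):
        gain = 1.0 + 0.5 * np.exp(
            -((np.fft.rfftfreq(N_FFT, 1 / FS) - 8e6) ** 2) / (2 * 2e6**2)
        )
        X = rng.normal(size=(40, N_FFT, 8)).astype(np.float32)
        zones = np.zeros(40, int)
        a = apply_transfer(X, tf_with_gain(gain), zones=zones, mode="fft")
        b = apply_transfer(X, tf_with_gain(gain), zones=zones, mode="fir")
        # agree in the interior (circular vs linear convolution differ at edges)
        core = slice(40, N_FFT - 40)
        rel = np.linalg.norm(a[:, core] - b[:, core]) / np.linalg.norm(a[:, core])
        assert rel < 0.05


class TestBidirectional:
    def test_identical_spectra_give_unity_in_high_snr_bins(self, rng):
        p = rng.uniform(1.0, 5.0, size=(2, 40))
        p[:, -1] = 1e-3  # explicit noise-floor bin
        fwd, bwd, snr = build_bidirectional(make_spectra(p), make_spectra(p))
        hi = snr.snr > 100
        assert hi.any()
        np.testing.assert_allclose(fwd.gamma_wiener[hi], 1.0, atol=0.01)
        np.testing.assert_allclose(bwd.gamma_wiener[hi], 1.0, atol=0.01)

    def test_calibrator_estimator_contract(self, rng):
        from sklearn.base import clone

        cal = M2MCalibrator(n_zones=1)
        clone(cal)
        X = rng.normal(size=(20, N_FFT, 6)).astype(np.float32)
        zones = np.zeros(20, int)
        cal.fit(X, X, zones=zones, zones_other=zones)
        assert cal.tf_forward_.direction == "train_to_test"
        out = cal.transform(X, zones=zones, direction="test_to_train")
        assert out.shape == X.shape
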