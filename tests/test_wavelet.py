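"""CWT analysis, universal soft-thresholding, reconstruction and the
denoising chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppglucose import synth, wavelet
from ppglucose.core import PPGSignal
from ppglucose.wavelet import (
    ScaleGrid,
    ThresholdSpec,
    WaveletCoefficients,
    WaveletSpec,
    cwt,
    denoise,
    estimate_noise_sigma,
    icwt,
    soft_threshold,
    universal_threshold,
)


def _coeffs(matrix, fs=100.0, family="mexican_hat"):
    spec = WaveletSpec(family)
    grid = ScaleGrid(np.geomspace(0.05, 1.0, matrix.shape[0]))
    return WaveletCoefficients(matrix=matrix, grid=grid, spec=spec, fs=fs)


class TestCWT:
    def test_zero_signal_gives_zero_coefficients(self):
        sig = PPGSignal(np.zeros(256), 100.0)
        co = cwt(sig, ScaleGrid.log_spaced(WaveletSpec()), WaveletSpec())
        assert np.allclose(co.matrix, 0.0)

    def test_linearity_in_amplitude(self, sine_signal):
        spec = WaveletSpec()
        grid = ScaleGrid.log_spaced(spec)
        c1 = cwt(sine_signal, grid, spec).matrix
        c3 = cwt(sine_signal.with_samples(3.0 * sine_signal.samples), grid, spec).matrix
        assert np.allclose(c3, 3.0 * c1, atol=1e-12)

    @pytest.mark.parametrize("family", ["mexican_hat", "morlet"])
    def test_sinusoid_peaks_at_predicted_scale(self, family):
        """For a pure tone the scale of maximal mean |coefficient| is
        the analytic maximizer of sqrt(a)*|psi_hat(a*w)| (the 1/sqrt(a)
        normalization contributes the sqrt(a) response factor), within
        one grid step."""
        fs = 100.0
        f_tone = 1.0
        t = np.arange(4096) / fs
        sig = PPGSignal(np.sin(2 * np.pi * f_tone * t), fs)
        spec = WaveletSpec(family)
        grid = ScaleGrid.log_spaced(spec, 0.25, 4.0, 48)
        co = cwt(sig, grid, spec)
        best = np.argmax(np.mean(np.abs(co.matrix), axis=1))
        a_dense = np.geomspace(grid.scales[0], grid.scales[-1], 4096)
        response = np.sqrt(a_dense) * np.abs(spec.psi_hat(a_dense * 2 * np.pi * f_tone))
        a_star = a_dense[np.argmax(response)]
        expected = int(np.argmin(np.abs(np.log(grid.scales) - np.log(a_star))))
        assert abs(best - expected) <= 1

    def test_matches_direct_integration_oracle(self):
        """FFT implementation equals brute-force discretization of the
        analysis integral at interior shifts."""
        fs = 50.0
        rng = np.random.default_rng(0)
        t = np.arange(512) / fs
        x = np.sin(2 * np.pi * 1.3 * t) + 0.3 * rng.standard_normal(t.size)
        sig = PPGSignal(x, fs)
        spec = WaveletSpec("mexican_hat")
        grid = ScaleGrid(np.array([0.2, 0.4, 0.8]))
        co = cwt(sig, grid, spec)
        dt = 1.0 / fs
        for si, a in enumerate(grid.scales):
            for b_idx in (200, 256, 300):
                b = t[b_idx]
                direct = np.sum(x * np.conj(spec.psi(((t - b) / a)))) * dt / np.sqrt(a)
                assert np.abs(co.matrix[si, b_idx] - direct) < 5e-3 * np.max(np.abs(co.matrix[si]))

    def test_nan_signal_rejected(self):
        with pytest.raises(ValueError):
            PPGSignal(np.array([1.0, np.nan, 2.0]), 100.0)

    def test_oversized_scale_warns(self):
        sig = PPGSignal(np.sin(np.arange(100)), 100.0)  # 1 s record
        grid = ScaleGrid(np.array([0.1, 2.0]))
        with pytest.warns(UserWarning, match="exceeds the signal duration"):
            cwt(sig, grid, WaveletSpec())


class TestUniversalThreshold:
    def test_single_point_threshold_is_zero(self):
        assert universal_threshold(5.0, 1).T == 0.0

    def test_closed_form_value(self):
        thr = universal_threshold(2.0, 1024)
        assert thr.T == pytest.approx(2.0 * np.sqrt(2.0 * np.log(1024)), abs=1e-12)
        assert thr.T == pytest.approx(7.446585, abs=1e-5)

    @given(st.integers(min_value=1, max_value=10**6), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_n(self, n, extra):
        assert universal_threshold(1.5, n + extra).T >= universal_threshold(1.5, n).T

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            universal_threshold(-0.1, 10)


class TestNoiseSigma:
    def test_zero_coefficients_give_zero(self):
        assert estimate_noise_sigma(_coeffs(np.zeros((4, 64)))) == 0.0

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((4, 256))
        assert estimate_noise_sigma(_coeffs(5.0 * m)) == pytest.approx(
            5.0 * estimate_noise_sigma(_coeffs(m))
        )

    def test_white_noise_estimate_within_15pct_of_monte_carlo(self):
        """Each seed's estimate stays within 15% of the 10-seed
        Monte-Carlo mean (the estimator's own sampling spread)."""
        spec = WaveletSpec()
        grid = ScaleGrid.log_spaced(spec)
        estimates = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0.0, 0.5, 4096)
            estimates.append(estimate_noise_sigma(cwt(PPGSignal(x, 100.0), grid, spec)))
        mc = np.mean(estimates)
        assert mc > 0
        assert np.all(np.abs(np.array(estimates) - mc) / mc < 0.15)


class TestSoftThreshold:
    @pytest.mark.parametrize("w,T,expected", [(1.5, 2.0, 0.0), (5.0, 2.0, 3.0), (-5.0, 2.0, -3.0)])
    def test_branch_cases(self, w, T, expected):
        co = _coeffs(np.full((2, 4), w))
        out = soft_threshold(co, ThresholdSpec(T=T, sigma=1.0, n_points=4))
        assert np.allclose(out.matrix, expected)

    @given(st.floats(min_value=0, max_value=10), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_contraction_and_energy(self, T, seed):
        m = np.random.default_rng(seed).standard_normal((3, 32))
        out = soft_threshold(_coeffs(m), ThresholdSpec(T=T, sigma=1.0, n_points=32))
        assert np.all(np.abs(out.matrix) <= np.abs(m) + 1e-15)
        assert np.sum(out.matrix**2) <= np.sum(m**2) + 1e-12
        assert np.all(np.sign(out.matrix[out.matrix != 0]) == np.sign(m[out.matrix != 0]))

    def test_identity_at_zero_threshold(self):
        m = np.random.default_rng(3).standard_normal((3, 16))
        out = soft_threshold(_coeffs(m), ThresholdSpec(T=0.0, sigma=0.0, n_points=16))
        assert np.allclose(out.matrix, m)

    def test_complex_modulus_shrunk_phase_preserved(self):
        m = np.array([[3 + 4j, 0.1 + 0.1j]])
        spec = WaveletSpec("morlet")
        co = WaveletCoefficients(m, ScaleGrid(np.array([0.5])), spec, 100.0)
        out = soft_threshold(co, ThresholdSpec(T=1.0, sigma=1.0, n_points=2)).matrix
        assert np.abs(out[0, 0]) == pytest.approx(4.0)
        assert np.angle(out[0, 0]) == pytest.approx(np.angle(m[0, 0]))
        assert out[0, 1] == 0


class TestICWT:
    def test_zero_coefficients_reconstruct_zero(self):
        spec = WaveletSpec()
        grid = ScaleGrid.log_spaced(spec)
        co = WaveletCoefficients(np.zeros((len(grid), 128)), grid, spec, 100.0)
        assert np.allclose(icwt(co).samples, 0.0)

    def test_linearity(self, sine_signal):
        spec = WaveletSpec()
        grid = ScaleGrid.log_spaced(spec)
        c1 = cwt(sine_signal, grid, spec)
        shifted = sine_signal.with_samples(np.roll(sine_signal.samples, 100))
        c2 = cwt(shifted, grid, spec)
        summed = WaveletCoefficients(c1.matrix + c2.matrix, grid, spec, 100.0)
        assert np.allclose(icwt(summed).samples, icwt(c1).samples + icwt(c2).samples, atol=1e-10)

    @pytest.mark.parametrize("family", ["mexican_hat", "morlet"])
    def test_round_trip_band_limited(self, family, sine_signal):
        spec = WaveletSpec(family)
        grid = ScaleGrid.log_spaced(spec, 0.125, 16.0, 64)
        rec = icwt(cwt(sine_signal, grid, spec)).samples
        rel = np.linalg.norm(rec - sine_signal.samples) / np.linalg.norm(sine_signal.samples)
        assert rel < 0.05


class TestDenoise:
    def test_clean_record_preserved(self, clean_record):
        out = denoise(clean_record.signal)
        assert len(out) == len(clean_record.signal)
        assert out.fs == clean_record.signal.fs
        r = np.corrcoef(out.samples, clean_record.signal.samples)[0, 1]
        assert r > 0.99

    def test_noise_rmse_reduced_on_noisy_records(self):
        """Denoising beats the identity on the AC (baseline-free)
        component for >= 9/10 noisy records."""
        wins = 0
        for seed in range(10):
            rec = synth.generate_record(
                synth.BeatModel(), synth.NoiseModel(white_sd=0.1), 150.0, 12.0, 100.0, seed=seed
            )
            clean_ac = rec.clean.samples - rec.clean.samples.mean()
            den = denoise(rec.signal)
            rmse_in = np.sqrt(np.mean((rec.signal.samples - rec.signal.samples.mean() - clean_ac) ** 2))
            rmse_out = np.sqrt(np.mean((den.samples - den.samples.mean() - clean_ac) ** 2))
            wins += rmse_out < rmse_in
        assert wins >= 9

    def test_baseline_drift_suppressed(self):
        rec = synth.generate_record(
            synth.BeatModel(), synth.NoiseModel.none(), 150.0, 20.0, 100.0, seed=3
        )
        t = rec.signal.times
        drifted = rec.signal.with_samples(rec.signal.samples + 5.0 * np.sin(2 * np.pi * 0.05 * t))
        out = denoise(drifted)
        design = np.column_stack([np.sin(2 * np.pi * 0.05 * t), np.cos(2 * np.pi * 0.05 * t)])
        coef, *_ = np.linalg.lstsq(design, out.samples, rcond=None)
        assert np.hypot(*coef) < 0.2 * 5.0
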