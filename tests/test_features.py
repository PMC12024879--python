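"""Feature estimators: closed-form cases, oracles, and the frozen
feature ordering."""

import numpy as np
import pytest

from ppglucose import synth
from ppglucose.acbs import CycleBoundaries, NormalizedCycle, PeakList, segment
from ppglucose.core import PPGSignal
from ppglucose.features import (
    FEATURE_NAMES,
    build_feature_matrix,
    extract,
    extract_from_record,
    frequency_domain,
    higuchi_fd,
    nonlinear,
    poincare_sd,
    shannon_entropy_bits,
    time_domain,
)


def _peaklist(times_s, fs=100.0):
    return PeakList(np.round(np.asarray(times_s) * fs).astype(int), fs)


class TestTimeDomain:
    def test_amplitude_uses_raw_segment(self):
        sig = PPGSignal(np.array([2.0, 4.0, 6.0, 4.0, 2.0]), 100.0)
        b = CycleBoundaries(starts=np.array([0]), ends=np.array([4]), Tf=1, n_peaks=1)
        cycles = [NormalizedCycle(np.interp(np.linspace(0, 4, 16), np.arange(5),
                                            (sig.samples - 2) / 4), (0.0, 0.04), 16)]
        out = time_domain(sig, _peaklist([0.02]), b, cycles)
        assert out["pulse_amplitude"] == pytest.approx(4.0)

    def test_uniform_peaks_give_ipi(self):
        sig = PPGSignal(np.zeros(400), 100.0)
        b = CycleBoundaries(starts=np.array([0]), ends=np.array([399]), Tf=1, n_peaks=3)
        cycle = NormalizedCycle(np.linspace(0, 1, 16), (0.0, 3.99), 16)
        out = time_domain(sig, _peaklist([1.0, 2.0, 3.0]), b, [cycle])
        assert out["ipi_s"] == pytest.approx(1.0)

    def test_triangle_upstroke_slope(self):
        """A ramp 0->1 over 0.25 s sampled at 100 Hz has slope 4/s."""
        fs = 100.0
        ramp = np.concatenate([np.linspace(0, 1, 26), np.linspace(1, 0, 26)[1:]])
        sig = PPGSignal(ramp, fs)
        b = CycleBoundaries(starts=np.array([0]), ends=np.array([50]), Tf=1, n_peaks=1)
        span = 50 / fs
        Lg = 51  # same grid as the source: slope is exact
        cycles = [NormalizedCycle(ramp, (0.0, span), Lg)]
        out = time_domain(sig, _peaklist([0.25]), b, cycles)
        assert out["upstroke_slope"] == pytest.approx(4.0, rel=0.05)
        assert out["downstroke_slope"] == pytest.approx(4.0, rel=0.05)

    def test_single_peak_marks_ipi_missing(self, clean_record):
        peaks, b, cycles = segment(clean_record.signal)
        single = PeakList(peaks.indices[:1], peaks.fs)
        out = time_domain(clean_record.signal, single, b, cycles)
        assert np.isnan(out["ipi_s"])
        assert np.isfinite(out["pulse_width_s"])


class TestFrequencyDomain:
    def test_constant_ipi_gives_zero_hrv(self):
        sig = PPGSignal(np.zeros(1200), 100.0)
        out = frequency_domain(sig, _peaklist([1, 2, 3, 4, 5]))
        assert out["hrv_sdnn_ms"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_tone_dominant_frequency(self):
        fs = 100.0
        t = np.arange(2000) / fs
        sig = PPGSignal(np.sin(2 * np.pi * 1.2 * t), fs)
        out = frequency_domain(sig, _peaklist([]))
        assert out["dominant_freq_hz"] == pytest.approx(1.2, abs=fs / (8 * fs))  # one bin

    def test_doubling_amplitude_adds_6db(self):
        fs = 100.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 1.2 * t)
        p1 = frequency_domain(PPGSignal(x, fs), _peaklist([]))["psd_db"]
        p2 = frequency_domain(PPGSignal(2 * x, fs), _peaklist([]))["psd_db"]
        assert p2 - p1 == pytest.approx(20 * np.log10(2), abs=0.01)

    def test_short_signal_gives_missing_markers(self):
        sig = PPGSignal(np.sin(np.arange(500) / 10), 100.0)  # 5 s
        out = frequency_domain(sig, _peaklist([]))
        assert np.isnan(out["psd_db"]) and np.isnan(out["dominant_freq_hz"])


class TestNonlinear:
    def test_constant_signal_has_zero_entropy(self):
        assert shannon_entropy_bits(np.full(256, 2.5)) == 0.0

    def test_uniform_histogram_has_four_bits(self):
        x = np.linspace(0, 1, 16 * 64)  # fills all 16 bins evenly
        assert shannon_entropy_bits(x, bins=16) == pytest.approx(4.0, abs=0.01)

    def test_constant_ipi_gives_zero_sd1_sd2(self):
        sd1, sd2 = poincare_sd(np.full(8, 0.8))
        assert sd1 == pytest.approx(0.0, abs=1e-9)
        assert sd2 == pytest.approx(0.0, abs=1e-9)

    def test_poincare_matches_rotation_oracle(self):
        """SD1/SD2 equal the SDs of the scatter rotated by 45 degrees
        with an explicit rotation matrix (independent construction)."""
        ipi_ms = np.array([800.0, 820.0, 790.0, 810.0])
        sd1, sd2 = poincare_sd(ipi_ms / 1000.0)
        pts = np.column_stack([ipi_ms[:-1], ipi_ms[1:]])
        theta = np.pi / 4
        rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
        rotated = pts @ rot.T
        assert sd2 == pytest.approx(np.std(rotated[:, 0], ddof=1))
        assert sd1 == pytest.approx(np.std(rotated[:, 1], ddof=1))

    def test_fd_orders_line_below_noise(self):
        n = 1024
        line = np.linspace(0, 1, n)
        noise = np.random.default_rng(0).standard_normal(n)
        assert higuchi_fd(line) < higuchi_fd(noise)
        assert 0.9 < higuchi_fd(line) < 1.1
        assert higuchi_fd(noise) > 1.5

    def test_insufficient_peaks_marked_missing(self):
        sig = PPGSignal(np.sin(np.arange(500) / 5), 100.0)
        out = nonlinear(sig, _peaklist([1.0, 2.0]))
        assert np.isnan(out["poincare_sd1_ms"])


class TestExtract:
    def test_thirteen_features_in_frozen_order(self, clean_record):
        vec = extract(*_segmented(clean_record))
        assert vec.values.size == 13
        assert vec.names == FEATURE_NAMES

    def test_identical_records_give_identical_rows(self, clean_record):
        v1 = extract_from_record(clean_record.signal)
        v2 = extract_from_record(clean_record.signal)
        assert np.array_equal(v1.values, v2.values)

    def test_time_shift_leaves_features_stable(self):
        """The same rhythm viewed through two offset windows yields
        nearly identical features."""
        rec = synth.generate_record(
            synth.BeatModel(hr_jitter_sd=0.0), synth.NoiseModel.none(), 120.0, 24.0, 100.0, seed=0
        )
        fs = 100.0
        period = int(0.8 * fs)
        a = PPGSignal(rec.signal.samples[: int(12 * fs)], fs)
        b = PPGSignal(rec.signal.samples[period : period + int(12 * fs)], fs)
        va, vb = extract_from_record(a).values, extract_from_record(b).values
        finite = np.isfinite(va) & np.isfinite(vb)
        assert np.allclose(va[finite], vb[finite], rtol=0.05, atol=0.02)

    def test_planted_pulse_width_effect_recovered(self):
        eff = synth.GlucoseEffectSpec(
            affected_features=("pulse_width_s",), effect_slopes=(1.2e-3,), informative_count=1
        )
        recs = synth.generate_records(50, noise=synth.NoiseModel.none(), effect=eff, seed=21)
        df = build_feature_matrix([r.signal for r in recs], bgl=[r.bgl for r in recs])
        r = np.corrcoef(df["bgl_mgdl"], df["pulse_width_s"])[0, 1]
        assert r > 0.5

    def test_unsegmentable_record_gives_nan_row(self):
        flat = PPGSignal(np.ones(1000), 100.0)
        assert np.all(np.isnan(extract_from_record(flat).values))
        with pytest.raises(ValueError):
            build_feature_matrix([flat])


def _segmented(record):
    peaks, b, cycles = segment(record.signal)
    return record.signal, peaks, b, cycles
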