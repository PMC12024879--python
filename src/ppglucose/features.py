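"""Per-record PPG feature extraction.

Thirteen features in a frozen order (time-domain, frequency-domain,
nonlinear), one scalar per record, aggregated as the mean over cycles
where a feature is cycle-wise:

time domain
    pulse width (s, between half-amplitude crossings of the normalized
    cycle), pulse amplitude (max - min of the raw segment, a.u.),
    inter-pulse interval (s), area under the normalized cycle (AUC,
    trapezoidal, over seconds), upstroke slope and downstroke slope
    (a.u./s, extreme forward differences of the normalized cycle).
frequency domain
    heart-rate variability (SDNN of the inter-pulse intervals, ms),
    total Welch band power in 0.5-8 Hz expressed in dB, and the
    dominant frequency (argmax of the Welch spectrum in 0.5-3 Hz).
nonlinear
    Higuchi fractal dimension (k_max = 8), Shannon entropy of a 16-bin
    amplitude histogram of the min-max-normalized record (bits), and
    Poincare SD1/SD2 of the inter-pulse intervals (ms, standard
    deviations of the 45-degree-rotated successive-interval scatter).

Features that cannot be computed (too few peaks, record too short for a
stable spectrum) are emitted as NaN; downstream stages drop or mask
such rows. The order of FEATURE_NAMES is part of the public contract:
feature-selection masks index into it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .acbs import CycleBoundaries, NormalizedCycle, PeakList, segment
from .core import PPGSignal

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "time_domain",
    "frequency_domain",
    "nonlinear",
    "extract",
    "extract_from_record",
    "build_feature_matrix",
    "higuchi_fd",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "pulse_width_s",
    "pulse_amplitude",
    "ipi_s",
    "auc",
    "upstroke_slope",
    "downstroke_slope",
    "hrv_sdnn_ms",
    "psd_db",
    "dominant_freq_hz",
    "fractal_dimension",
    "entropy_bits",
    "poincare_sd1_ms",
    "poincare_sd2_ms",
)

#: Band (Hz) integrated for the power feature and searched for the
#: dominant frequency.
PSD_BAND = (0.5, 8.0)
DOMINANT_BAND = (0.5, 3.0)
#: Minimum record length (s) for stable spectral estimates.
MIN_SPECTRUM_DURATION = 10.0


@dataclass(frozen=True)
class FeatureVector:
    """d feature values in FEATURE_NAMES order (NaN = not computable)."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size != len(self.names):
            raise ValueError(f"{values.size} values for {len(self.names)} names")
        object.__setattr__(self, "values", values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _half_amplitude_width(cycle: NormalizedCycle) -> float:
    """Time between the first and last half-amplitude crossings, s."""
    v = cycle.values
    above = v >= 0.5
    if not above.any():
        return np.nan
    first = int(np.argmax(above))
    last = int(v.size - 1 - np.argmax(above[::-1]))
    # linear interpolation to sub-sample crossing positions
    t_first = float(first)
    if first > 0 and v[first] > v[first - 1]:
        t_first = first - 1 + (0.5 - v[first - 1]) / (v[first] - v[first - 1])
    t_last = float(last)
    if last < v.size - 1 and v[last] > v[last + 1]:
        t_last = last + (v[last] - 0.5) / (v[last] - v[last + 1])
    dt = cycle.duration / (cycle.Lg - 1)
    return (t_last - t_first) * dt


def time_domain(
    signal: PPGSignal,
    peaks: PeakList,
    b: CycleBoundaries,
    cycles: list[NormalizedCycle],
) -> dict[str, float]:
    """Cycle-averaged time-domain features.

    Pulse amplitude is computed on the raw segment (the normalized
    cycle has amplitude 1 by construction); slopes and AUC use the
    normalized cycle with its own resampled rate.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    widths, amps, aucs, ups, downs = [], [], [], [], []
    for (start, end), cycle in zip(zip(b.starts, b.ends), cycles):
        seg = signal.samples[start : end + 1]
        amps.append(float(seg.max() - seg.min()))
        widths.append(_half_amplitude_width(cycle))
        fs_cycle = (cycle.Lg - 1) / cycle.duration
        diffs = np.diff(cycle.values)
        ups.append(float(diffs.max() * fs_cycle))
        downs.append(float(abs(diffs.min()) * fs_cycle))
        aucs.append(float(np.trapezoid(cycle.values, dx=1.0 / fs_cycle)))
    ipi = float(np.mean(peaks.intervals())) if len(peaks) >= 2 else np.nan
    return {
        "pulse_width_s": float(np.nanmean(widths)),
        "pulse_amplitude": float(np.mean(amps)),
        "ipi_s": ipi,
        "auc": float(np.mean(aucs)),
        "upstroke_slope": float(np.mean(ups)),
        "downstroke_slope": float(np.mean(downs)),
    }


def frequency_domain(signal: PPGSignal, peaks: PeakList) -> dict[str, float]:
    """HRV (SDNN), band power in dB, and dominant frequency.

    Records shorter than MIN_SPECTRUM_DURATION give NaN for the
    spectral features; fewer than three peaks give NaN HRV.
    """
    out = {"hrv_sdnn_ms": np.nan, "psd_db": np.nan, "dominant_freq_hz": np.nan}
    if len(peaks) >= 3:
        out["hrv_sdnn_ms"] = float(np.std(peaks.intervals(), ddof=1) * 1000.0)
    if signal.duration < MIN_SPECTRUM_DURATION:
        return out
    nperseg = min(len(signal), int(round(8 * signal.fs)))
    freqs, psd = welch(signal.samples, fs=signal.fs, nperseg=nperseg)
    band = (freqs >= PSD_BAND[0]) & (freqs <= PSD_BAND[1])
    power = float(np.trapezoid(psd[band], freqs[band]))
    if power > 0:
        out["psd_db"] = float(10.0 * np.log10(power))
    dom = (freqs >= DOMINANT_BAND[0]) & (freqs <= DOMINANT_BAND[1])
    if dom.any():
        out["dominant_freq_hz"] = float(freqs[dom][np.argmax(psd[dom])])
    return out


def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi's fractal dimension of a 1-D series.

    Builds k decimated sub-series for each delay k = 1..k_max, averages
    their normalized curve lengths L(k), and returns the slope of
    log L(k) against log(1/k). Between 1 (smooth) and 2 (plane-filling).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * k_max:
        return np.nan
    lengths = []
    for k in range(1, k_max + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lm.append(dist * norm / k)
        lengths.append(np.mean(lm))
    k_arr = np.arange(1, k_max + 1)
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        return np.nan
    slope, _ = np.polyfit(np.log(1.0 / k_arr), np.log(lengths), 1)
    return float(slope)


def shannon_entropy_bits(x: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy of the amplitude histogram of min-max normalized
    x, in bits. A constant signal occupies one bin: zero entropy."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram((x - lo) / (hi - lo), bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def poincare_sd(intervals_s: np.ndarray) -> tuple[float, float]:
    """SD1/SD2 of the Poincare scatter of successive intervals, in ms.

    The scatter of (x_i, x_{i+1}) is rotated by 45 degrees; SD1 is the
    sample SD along the minor axis (x_{i+1} - x_i)/sqrt(2), SD2 along
    the major axis (x_{i+1} + x_i)/sqrt(2).
    """
    x = np.asarray(intervals_s, dtype=float) * 1000.0
    if x.size < 3:
        return np.nan, np.nan
    head, tail = x[:-1], x[1:]
    minor = (tail - head) / np.sqrt(2.0)
    major = (tail + head) / np.sqrt(2.0)
    return float(np.std(minor, ddof=1)), float(np.std(major, ddof=1))


def nonlinear(signal: PPGSignal, peaks: PeakList) -> dict[str, float]:
    """Fractal dimension, amplitude entropy and Poincare SD1/SD2."""
    out = {
        "fractal_dimension": np.nan,
        "entropy_bits": np.nan,
        "poincare_sd1_ms": np.nan,
        "poincare_sd2_ms": np.nan,
    }
    if len(signal) >= 64:
        out["fractal_dimension"] = higuchi_fd(signal.samples, k_max=8)
        out["entropy_bits"] = shannon_entropy_bits(signal.samples, bins=16)
    if len(peaks) >= 4:  # >= 3 inter-pulse intervals
        sd1, sd2 = poincare_sd(peaks.intervals())
        out["poincare_sd1_ms"] = sd1
        out["poincare_sd2_ms"] = sd2
    return out


def extract(
    signal: PPGSignal,
    peaks: PeakList,
    b: CycleBoundaries,
    cycles: list[NormalizedCycle],
) -> FeatureVector:
    """Concatenate the three feature groups in FEATURE_NAMES order."""
    merged = {}
    merged.update(time_domain(signal, peaks, b, cycles))
    merged.update(frequency_domain(signal, peaks))
    merged.update(nonlinear(signal, peaks))
    return FeatureVector(values=np.array([merged[name] for name in FEATURE_NAMES]))


def extract_from_record(
    signal: PPGSignal,
    Lg: int = 100,
    min_hr: float = 40.0,
    max_hr: float = 180.0,
) -> FeatureVector:
    """Segment a record and extract its feature vector.

    A record that cannot be segmented (no detectable beats) yields an
    all-NaN vector so callers can drop it with bookkeeping.
    """
    try:
        peaks, b, cycles = segment(signal, Lg=Lg, min_hr=min_hr, max_hr=max_hr)
    except ValueError:
        logger.warning("record could not be segmented; emitting all-NaN features")
        return FeatureVector(values=np.full(len(FEATURE_NAMES), np.nan))
    return extract(signal, peaks, b, cycles)


def build_feature_matrix(
    signals: list[PPGSignal],
    bgl: list[float] | None = None,
    glucose_class: list[str] | None = None,
    Lg: int = 100,
    min_hr: float = 40.0,
    max_hr: float = 180.0,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Feature matrix (one row per record) with optional label columns
    ``bgl_mgdl`` and ``class``.

    Rows with any NaN feature are dropped (with a logged count) when
    ``drop_incomplete`` is set: the selector and trainer require
    complete rows.
    """
    rows = [extract_from_record(s, Lg=Lg, min_hr=min_hr, max_hr=max_hr).values for s in signals]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if bgl is not None:
        df["bgl_mgdl"] = list(bgl)
    if glucose_class is not None:
        df["class"] = list(glucose_class)
    if drop_incomplete:
        complete = ~df[list(FEATURE_NAMES)].isna().any(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropped %d/%d records with incomplete features", n_dropped, len(df))
        df = df.loc[complete].reset_index(drop=True)
    if df.empty:
        raise ValueError("no records produced a complete feature vector")
    return df
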