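"""Adaptive cycle-based segmentation (ACBS) of PPG signals.

Cuts a denoised PPG trace into one segment per heartbeat: systolic
peaks are detected from the first derivative with an adaptive
threshold, cycle boundaries are placed midway between consecutive
peaks (with fixed windows at the record edges), and each cycle is
resampled to a common length and min-max normalized to [0, 1] so that
downstream feature extraction sees heart-rate- and gain-invariant
waveforms.

Peak detection detail: maxima of the first derivative mark the point of
steepest systolic upstroke, which slightly precedes the waveform peak.
Candidates are therefore taken at derivative maxima that exceed an
adaptive threshold (half the rolling 2-s upper quartile of the positive
derivative — scale-invariant by construction) and then snapped to the
largest signal value within the following 0.2 s. A refractory interval
of 60/max_hr seconds suppresses double detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import percentile_filter

from .core import PPGSignal

__all__ = [
    "PeakList",
    "CycleBoundaries",
    "NormalizedCycle",
    "detect_peaks",
    "boundaries",
    "extract_cycles",
    "segment",
]

logger = logging.getLogger(__name__)

#: Window (s) searched after a steep-upstroke candidate for the peak.
SNAP_WINDOW_S = 0.2
#: Span (s) of the rolling window behind the adaptive threshold.
THRESHOLD_WINDOW_S = 2.0
#: Threshold = this fraction of the rolling upper quartile.
THRESHOLD_FRACTION = 0.5


@dataclass(frozen=True)
class PeakList:
    """Detected systolic peak positions (sample indices), ascending."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("peak indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds from the start of the record."""
        return self.indices / self.fs

    def intervals(self) -> np.ndarray:
        """Inter-pulse intervals in seconds (length = n_peaks - 1)."""
        return np.diff(self.indices) / self.fs


@dataclass(frozen=True)
class CycleBoundaries:
    """Per-cycle [start, end] sample positions; interior cycles tile the
    signal (end of cycle k = start of cycle k+1)."""

    starts: np.ndarray
    ends: np.ndarray
    Tf: int
    n_peaks: int

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=int)
        ends = np.asarray(self.ends, dtype=int)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        if np.any(starts >= ends):
            raise ValueError("every cycle needs start < end")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    def __len__(self) -> int:
        return self.starts.size


@dataclass(frozen=True)
class NormalizedCycle:
    """One heartbeat, resampled to Lg samples and scaled to [0, 1]."""

    values: np.ndarray
    source_span: tuple[float, float]
    Lg: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size != self.Lg:
            raise ValueError(f"cycle length {values.size} != Lg {self.Lg}")
        object.__setattr__(self, "values", values)

    @property
    def duration(self) -> float:
        return self.source_span[1] - self.source_span[0]


def detect_peaks(signal: PPGSignal, min_hr: float = 40.0, max_hr: float = 180.0) -> PeakList:
    """Detect systolic peaks in a (denoised) PPG signal.

    Returns an empty list — not an error — when the record is shorter
    than one maximum beat period or contains no qualifying upstrokes
    (e.g. a constant signal has zero derivative everywhere).
    """
    if not (0 < min_hr < max_hr):
        raise ValueError("need 0 < min_hr < max_hr")
    x = signal.samples
    fs = signal.fs
    max_period = 60.0 / min_hr
    if signal.duration < max_period:
        return PeakList(indices=np.array([], dtype=int), fs=fs)

    deriv = np.gradient(x) * fs
    pos = np.maximum(deriv, 0.0)
    win = max(3, int(round(THRESHOLD_WINDOW_S * fs)))
    threshold = THRESHOLD_FRACTION * percentile_filter(pos, 75, size=win, mode="nearest")

    # candidate = local maximum of the derivative strictly above threshold
    rising = np.flatnonzero(
        (deriv[1:-1] > deriv[:-2]) & (deriv[1:-1] >= deriv[2:]) & (deriv[1:-1] > threshold[1:-1])
    ) + 1
    if rising.size == 0:
        return PeakList(indices=np.array([], dtype=int), fs=fs)

    snap = max(1, int(round(SNAP_WINDOW_S * fs)))
    candidates = []
    for c in rising:
        stop = min(x.size, c + snap + 1)
        candidates.append(c + int(np.argmax(x[c:stop])))

    # one sample of slack tolerates sample-grid rounding of beats at
    # exactly the max_hr period
    refractory = max(1, int(round(60.0 / max_hr * fs)) - 1)
    accepted: list[int] = []
    for c in candidates:
        if not accepted:
            accepted.append(c)
            continue
        if c == accepted[-1]:
            continue
        if c - accepted[-1] < refractory:
            if x[c] > x[accepted[-1]]:
                accepted[-1] = c  # keep the taller of the colliding pair
        else:
            accepted.append(c)
    return PeakList(indices=np.asarray(accepted, dtype=int), fs=fs)


def default_fixed_window(peaks: PeakList) -> int:
    """Edge window Tf: half the median inter-peak interval, in samples
    (0.5 s when fewer than two peaks are available)."""
    if len(peaks) >= 2:
        return max(1, int(np.median(np.diff(peaks.indices)) // 2))
    return max(1, int(round(0.5 * peaks.fs)))


def boundaries(peaks: PeakList, Tf: int | None, signal_len: int) -> CycleBoundaries:
    """Cycle boundaries from a peak list.

    Interior boundaries sit midway between consecutive peaks (floor
    division, so ties break deterministically toward the earlier
    sample); the first start and last end extend a fixed window Tf from
    the outer peaks and are clipped to [0, signal_len).
    """
    if len(peaks) == 0:
        raise ValueError("cannot build cycle boundaries from an empty peak list")
    if Tf is None:
        Tf = default_fixed_window(peaks)
    if Tf <= 0:
        raise ValueError("Tf must be positive")
    idx = peaks.indices
    mids = (idx[:-1] + idx[1:]) // 2
    starts = np.concatenate(([idx[0] - Tf], mids))
    ends = np.concatenate((mids, [idx[-1] + Tf]))
    starts = np.clip(starts, 0, signal_len - 1)
    ends = np.clip(ends, 0, signal_len - 1)
    return CycleBoundaries(starts=starts, ends=ends, Tf=int(Tf), n_peaks=len(peaks))


def extract_cycles(signal: PPGSignal, b: CycleBoundaries, Lg: int = 100) -> list[NormalizedCycle]:
    """Extract, resample and normalize every cycle.

    Each segment (boundary samples inclusive) is linearly interpolated
    to exactly Lg samples and min-max scaled to [0, 1]. A degenerate
    flat segment (max == min) yields an all-zero cycle and a logged
    warning rather than an error.
    """
    if Lg < 8:
        raise ValueError(f"Lg must be >= 8, got {Lg}")
    x = signal.samples
    cycles = []
    for start, end in zip(b.starts, b.ends):
        seg = x[start : end + 1]
        grid = np.linspace(0.0, seg.size - 1.0, Lg)
        resampled = np.interp(grid, np.arange(seg.size), seg)
        lo, hi = resampled.min(), resampled.max()
        if hi > lo:
            values = (resampled - lo) / (hi - lo)
        else:
            logger.warning("degenerate flat cycle at samples [%d, %d]; emitting zeros", start, end)
            values = np.zeros(Lg)
        cycles.append(
            NormalizedCycle(
                values=values,
                source_span=(signal.t0 + start / signal.fs, signal.t0 + end / signal.fs),
                Lg=Lg,
            )
        )
    return cycles


def segment(
    signal: PPGSignal,
    Lg: int = 100,
    min_hr: float = 40.0,
    max_hr: float = 180.0,
    Tf: int | None = None,
) -> tuple[PeakList, CycleBoundaries, list[NormalizedCycle]]:
    """Full ACBS pass: peaks -> boundaries -> normalized cycles.

    Raises ValueError when no peaks are found (nothing to segment).
    """
    peaks = detect_peaks(signal, min_hr=min_hr, max_hr=max_hr)
    if len(peaks) == 0:
        raise ValueError("no peaks detected; cannot segment the record")
    b = boundaries(peaks, Tf, len(signal))
    return peaks, b, extract_cycles(signal, b, Lg)
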