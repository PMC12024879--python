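"""Core container for photoplethysmogram (PPG) time series.

A PPG trace is a uniformly sampled optical blood-volume signal: one
quasi-periodic pulse per heartbeat, typically a sharp systolic peak
followed by a smaller dicrotic component. Everything downstream
(denoising, beat segmentation, feature extraction) consumes this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPGSignal"]


@dataclass(frozen=True)
class PPGSignal:
    """Uniformly sampled single-channel PPG signal.

    Parameters
    ----------
    samples : ndarray
        Signal amplitudes in arbitrary units; finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float, optional
        Start time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 2:
            raise ValueError("signal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal span in seconds (n samples at rate fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "PPGSignal":
        """Return a copy carrying new samples but the same fs and t0."""
        return PPGSignal(samples=np.asarray(samples, dtype=float), fs=self.fs, t0=self.t0)
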