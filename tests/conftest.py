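import numpy as np
import pytest

from ppglucose import synth
from ppglucose.core import PPGSignal


@pytest.fixture
def clean_record():
    """Regular 60-bpm noiseless record: 10 s at 100 Hz, 10 beats."""
    return synth.generate_record(
        synth.BeatModel(heart_rate=60.0, hr_jitter_sd=0.0),
        synth.NoiseModel.none(),
        bgl=120.0,
        duration=10.0,
        fs=100.0,
        seed=1234,
    )


@pytest.fixture
def sine_signal():
    """Band-limited test signal: 1 Hz + 2.3 Hz tones, ~20 s at 100 Hz."""
    fs = 100.0
    t = np.arange(2048) / fs
    x = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 2.3 * t)
    return PPGSignal(x, fs)
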