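"""Synthetic PPG generator with known beat times and glucose labels.

Emulates, at desk scale, what a bedside PPG recording session provides:
a quasi-periodic pulse train (systolic peak plus a delayed dicrotic
component), slow baseline drift, broadband sensor noise, occasional
motion artifacts, and a per-record reference blood-glucose level (BGL)
in mg/dL. A configurable glucose->morphology link makes the glucose
signal recoverable by the downstream feature-selection and federated
training stages, so the whole pipeline can be exercised and tested
without access to clinical recordings.

The waveform model is deliberately simple — each beat is the sum of two
Gaussians — which is enough to expose every morphological feature the
feature module computes. It is not a physiologically validated
pulse-wave model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import PPGSignal

__all__ = [
    "BeatModel",
    "NoiseModel",
    "GlucoseEffectSpec",
    "SyntheticRecord",
    "label_class",
    "generate_record",
    "generate_records",
    "generate_federated_datasets",
    "planted_feature_matrix",
    "DEFAULT_CLASS_THRESHOLDS",
    "REFERENCE_BGL",
    "DEFAULT_BGL_RANGE",
]

#: Clinical hypo/hyper cut-offs in mg/dL (70-180 band = normoglycemia).
DEFAULT_CLASS_THRESHOLDS: tuple[float, float] = (70.0, 180.0)

#: BGL at which the glucose->morphology modulation is neutral (mg/dL).
REFERENCE_BGL: float = 125.0

#: Default sampling range for per-record reference BGLs (mg/dL).
DEFAULT_BGL_RANGE: tuple[float, float] = (50.0, 300.0)

#: Heterogeneity unit: a heterogeneity of 1.0 spreads client BGL means
#: by up to +-25 mg/dL.
HETEROGENEITY_BGL_SCALE: float = 25.0


@dataclass(frozen=True)
class BeatModel:
    """Morphology of a single synthetic heartbeat.

    Each beat contributes ``systolic_amp * G(t; systolic_width)`` plus a
    delayed, wider dicrotic bump ``dicrotic_amp * G(t - dicrotic_delay)``
    where G is a unit-height Gaussian. The dicrotic width is fixed at
    1.6x the systolic width.

    Parameters
    ----------
    heart_rate : float
        Mean heart rate in beats/min, in (20, 250).
    systolic_amp, dicrotic_amp : float
        Peak heights in arbitrary units; the dicrotic component must be
        the smaller of the two.
    systolic_width : float
        Gaussian standard deviation of the systolic peak, seconds.
    dicrotic_delay : float
        Delay of the dicrotic bump behind the systolic peak, seconds.
    hr_jitter_sd : float
        SD of the Gaussian jitter added to each inter-beat interval,
        seconds. Zero gives a perfectly regular rhythm.
    """

    heart_rate: float = 75.0
    systolic_amp: float = 1.0
    systolic_width: float = 0.10
    dicrotic_amp: float = 0.35
    dicrotic_delay: float = 0.25
    hr_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (20.0 < self.heart_rate < 250.0):
            raise ValueError(f"heart_rate must be in (20, 250) bpm, got {self.heart_rate}")
        if self.systolic_width <= 0 or self.dicrotic_delay <= 0:
            raise ValueError("systolic_width and dicrotic_delay must be positive")
        if not (0 <= self.dicrotic_amp < self.systolic_amp):
            raise ValueError("dicrotic_amp must be non-negative and below systolic_amp")
        if self.hr_jitter_sd < 0:
            raise ValueError("hr_jitter_sd must be non-negative")

    @property
    def period(self) -> float:
        """Mean inter-beat interval in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class NoiseModel:
    """Additive corruption applied on top of the clean pulse train.

    white_sd is the SD of Gaussian sensor noise; drift is a sinusoidal
    baseline wander of amplitude ``drift_amp`` at ``drift_freq`` Hz with
    a random phase; motion artifacts are Gaussian bumps of random sign
    and ~0.3 s width arriving as a Poisson process at ``artifact_rate``
    events/min with amplitude ``artifact_amp``.
    """

    white_sd: float = 0.05
    drift_amp: float = 0.30
    drift_freq: float = 0.08
    artifact_rate: float = 2.0
    artifact_amp: float = 0.8

    def __post_init__(self) -> None:
        for name in ("white_sd", "drift_amp", "drift_freq", "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """A silent noise model (clean analytic waveform)."""
        return cls(white_sd=0.0, drift_amp=0.0, drift_freq=0.0, artifact_rate=0.0, artifact_amp=0.0)


# Morphology handle each affected feature maps onto. Slopes are
# fractional change of the handle per mg/dL away from REFERENCE_BGL.
_EFFECT_HANDLES = {
    "pulse_width_s": "systolic_width",
    "pulse_amplitude": "systolic_amp",
}


@dataclass(frozen=True)
class GlucoseEffectSpec:
    """Link between a record's BGL and its beat morphology.

    For an affected feature with slope s, the corresponding morphology
    parameter p of :class:`BeatModel` becomes
    ``p * (1 + s * (bgl - REFERENCE_BGL))``, so the induced correlation
    between BGL and the feature carries the sign of s. Supported
    features: ``pulse_width_s`` (scales the systolic width) and
    ``pulse_amplitude`` (scales the systolic amplitude); both propagate
    into AUC, upstroke/downstroke slope etc.
    """

    affected_features: tuple[str, ...] = ("pulse_width_s", "pulse_amplitude")
    effect_slopes: tuple[float, ...] = (1.2e-3, 1.6e-3)
    informative_count: int = 2

    def __post_init__(self) -> None:
        if len(self.affected_features) != len(self.effect_slopes):
            raise ValueError("affected_features and effect_slopes must have equal length")
        if self.informative_count > len(self.affected_features):
            raise ValueError("informative_count exceeds the number of affected features")
        for name in self.affected_features:
            if name not in _EFFECT_HANDLES:
                raise ValueError(
                    f"unsupported affected feature {name!r}; supported: {sorted(_EFFECT_HANDLES)}"
                )
        if not all(math.isfinite(s) for s in self.effect_slopes):
            raise ValueError("effect slopes must be finite")

    @classmethod
    def none(cls) -> "GlucoseEffectSpec":
        """No glucose->morphology coupling."""
        return cls(affected_features=(), effect_slopes=(), informative_count=0)

    def apply(self, beat: BeatModel, bgl: float) -> BeatModel:
        """Return the beat model modulated for a record at ``bgl`` mg/dL."""
        changes: dict[str, float] = {}
        for name, slope in zip(self.affected_features, self.effect_slopes):
            handle = _EFFECT_HANDLES[name]
            base = getattr(beat, handle)
            changes[handle] = base * (1.0 + slope * (bgl - REFERENCE_BGL))
        return replace(beat, **changes) if changes else beat


@dataclass(frozen=True)
class SyntheticRecord:
    """One generated PPG record with its ground truth.

    beat_times are the systolic peak times of the clean waveform (the
    generator's ground truth for segmentation tests); bgl is the
    reference glucose in mg/dL and glucose_class its clinical band.
    """

    signal: PPGSignal
    beat_times: np.ndarray
    bgl: float
    glucose_class: str
    subject_id: str
    clean: PPGSignal | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.size and np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        t_end = self.signal.t0 + self.signal.duration
        if bt.size and (bt[0] < self.signal.t0 or bt[-1] > t_end):
            raise ValueError("beat_times must lie inside the signal span")
        if not (self.bgl > 0):
            raise ValueError("bgl must be positive")
        object.__setattr__(self, "beat_times", bt)


def label_class(bgl: float, thresholds: tuple[float, float] = DEFAULT_CLASS_THRESHOLDS) -> str:
    """Classify a BGL into hypo/normo/hyperglycemia.

    The band is closed: ``low <= bgl <= high`` is normoglycemia.
    """
    low, high = thresholds
    if not (0 < low < high):
        raise ValueError(f"thresholds must satisfy 0 < low < high, got {thresholds}")
    if not (bgl > 0):
        raise ValueError(f"bgl must be positive, got {bgl}")
    if bgl < low:
        return "hypo"
    if bgl > high:
        return "hyper"
    return "normo"


CLASS_NAMES: tuple[str, str, str] = ("hypo", "normo", "hyper")


def _beat_times(beat: BeatModel, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Beat schedule: first beat half a period in, then period + jitter.

    With zero jitter this places exactly floor(duration / period) beats
    in the record (one beat per inter-beat interval that fits).
    """
    times = []
    t = 0.5 * beat.period
    while t < duration:
        times.append(t)
        step = beat.period
        if beat.hr_jitter_sd > 0:
            step += beat.hr_jitter_sd * rng.standard_normal()
            step = max(step, 0.25 * beat.period)  # keep the rhythm physical
        t += step
    return np.asarray(times)


def _pulse_train(t: np.ndarray, beat: BeatModel, beat_times: np.ndarray) -> np.ndarray:
    """Clean waveform: two Gaussians per beat (systolic + dicrotic)."""
    out = np.zeros_like(t)
    ws = beat.systolic_width
    wd = 1.6 * ws
    # cap the dicrotic delay at 40% of the period so high heart rates
    # do not push the bump into the next beat
    delay = min(beat.dicrotic_delay, 0.4 * beat.period)
    for bt in beat_times:
        out += beat.systolic_amp * np.exp(-0.5 * ((t - bt) / ws) ** 2)
        out += beat.dicrotic_amp * np.exp(-0.5 * ((t - bt - delay) / wd) ** 2)
    return out


def _noise_trace(
    t: np.ndarray, noise: NoiseModel, duration: float, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros_like(t)
    if noise.drift_amp > 0 and noise.drift_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.drift_amp * np.sin(2 * np.pi * noise.drift_freq * t + phase)
    if noise.artifact_rate > 0 and noise.artifact_amp > 0:
        n_events = rng.poisson(noise.artifact_rate * duration / 60.0)
        for _ in range(n_events):
            center = rng.uniform(0, duration)
            width = rng.uniform(0.15, 0.5)
            sign = rng.choice([-1.0, 1.0])
            out += sign * noise.artifact_amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    if noise.white_sd > 0:
        out += noise.white_sd * rng.standard_normal(t.size)
    return out


def generate_record(
    beat: BeatModel,
    noise: NoiseModel,
    bgl: float,
    duration: float,
    fs: float,
    seed: int | np.random.SeedSequence,
    effect: GlucoseEffectSpec | None = None,
    subject_id: str = "synthetic",
    thresholds: tuple[float, float] = DEFAULT_CLASS_THRESHOLDS,
) -> SyntheticRecord:
    """Generate one synthetic PPG record.

    Parameters
    ----------
    beat, noise : BeatModel, NoiseModel
        Waveform morphology and corruption model.
    bgl : float
        Reference blood glucose in mg/dL; if ``effect`` is given it
        modulates the beat morphology before synthesis.
    duration, fs : float
        Record length (s, must exceed two beat periods) and sampling
        rate (Hz, >= 50).
    seed : int or SeedSequence
        Drives all randomness; identical seeds give identical records.

    Returns
    -------
    SyntheticRecord
        With the noisy signal, ground-truth beat times, the clean
        waveform (``.clean``), and the glucose class label.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if fs < 50:
        raise ValueError(f"fs must be at least 50 Hz, got {fs}")
    if duration <= 2 * beat.period:
        raise ValueError(
            f"duration {duration} s must exceed two beat periods ({2 * beat.period:.2f} s)"
        )
    rng = np.random.default_rng(seed)
    eff_beat = effect.apply(beat, bgl) if effect is not None else beat
    n = round(duration * fs)
    t = np.arange(n) / fs
    beat_times = _beat_times(eff_beat, duration, rng)
    clean = _pulse_train(t, eff_beat, beat_times)
    noisy = clean + _noise_trace(t, noise, duration, rng)
    return SyntheticRecord(
        signal=PPGSignal(noisy, fs=fs),
        beat_times=beat_times,
        bgl=float(bgl),
        glucose_class=label_class(bgl, thresholds),
        subject_id=subject_id,
        clean=PPGSignal(clean, fs=fs),
    )


def _generate_batch(
    children: list[np.random.SeedSequence],
    beat: BeatModel,
    noise: NoiseModel,
    effect: GlucoseEffectSpec | None,
    duration: float,
    fs: float,
    bgl_range: tuple[float, float],
    bgl_offset: float,
    white_sd_scale: float,
    subject_prefix: str,
) -> list[SyntheticRecord]:
    lo, hi = bgl_range
    eff_noise = replace(noise, white_sd=noise.white_sd * white_sd_scale)
    records = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        bgl = float(np.clip(rng.uniform(lo, hi) + bgl_offset, 40.0, 400.0))
        rec = generate_record(
            beat,
            eff_noise,
            bgl,
            duration,
            fs,
            seed=rng,
            effect=effect,
            subject_id=f"{subject_prefix}{i:04d}",
        )
        records.append(rec)
    return records


def generate_records(
    n: int,
    beat: BeatModel | None = None,
    noise: NoiseModel | None = None,
    effect: GlucoseEffectSpec | None = None,
    duration: float = 12.0,
    fs: float = 100.0,
    bgl_range: tuple[float, float] = DEFAULT_BGL_RANGE,
    seed: int | np.random.SeedSequence = 0,
    subject_prefix: str = "rec",
) -> list[SyntheticRecord]:
    """Generate ``n`` independent records with BGLs uniform on ``bgl_range``.

    The BGL distribution of real cohorts is unknown here; uniform over
    50-300 mg/dL covers all three clinical classes without claiming
    fidelity to any population.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    beat = beat or BeatModel()
    noise = noise or NoiseModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)  # last child reserved for auxiliary draws
    return _generate_batch(
        children[:n], beat, noise, effect, duration, fs, bgl_range, 0.0, 1.0, subject_prefix
    )


def generate_client_records(
    n_clients: int,
    records_per_client: list[int],
    beat: BeatModel | None = None,
    noise: NoiseModel | None = None,
    effect: GlucoseEffectSpec | None = None,
    heterogeneity: float = 0.0,
    duration: float = 12.0,
    fs: float = 100.0,
    bgl_range: tuple[float, float] = DEFAULT_BGL_RANGE,
    seed: int | np.random.SeedSequence = 0,
) -> list[list[SyntheticRecord]]:
    """Per-client record lists for a simulated federation.

    ``heterogeneity`` (>= 0) emulates cross-site diversity: each client's
    BGL mean is shifted by ``heterogeneity * 25 mg/dL * u`` with
    u ~ U(-1, 1), and its sensor noise SD is scaled by a factor in
    ``1 +- heterogeneity/2``. At heterogeneity 0 every client draws from
    the same distribution, and with a single client the output equals
    pooled :func:`generate_records` at the same seed.
    """
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if not records_per_client:
        raise ValueError("records_per_client must be non-empty")
    if len(records_per_client) != n_clients:
        raise ValueError("records_per_client must list one size per client")
    if any(s < 1 for s in records_per_client):
        raise ValueError("client sizes must be positive")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be non-negative")
    beat = beat or BeatModel()
    noise = noise or NoiseModel()
    n_total = int(sum(records_per_client))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_total + 1)
    aux = np.random.default_rng(children[-1])
    if heterogeneity > 0:
        offsets = heterogeneity * HETEROGENEITY_BGL_SCALE * aux.uniform(-1, 1, n_clients)
        noise_scales = 1.0 + heterogeneity * aux.uniform(-0.5, 0.5, n_clients)
    else:
        offsets = np.zeros(n_clients)
        noise_scales = np.ones(n_clients)
    out: list[list[SyntheticRecord]] = []
    start = 0
    for i, size in enumerate(records_per_client):
        out.append(
            _generate_batch(
                children[start : start + size],
                beat,
                noise,
                effect,
                duration,
                fs,
                bgl_range,
                float(offsets[i]),
                float(noise_scales[i]),
                subject_prefix=f"client{i}_",
            )
        )
        start += size
    return out


def generate_federated_datasets(
    n_clients: int,
    records_per_client: list[int],
    effect: GlucoseEffectSpec | None = None,
    heterogeneity: float = 0.0,
    beat: BeatModel | None = None,
    noise: NoiseModel | None = None,
    duration: float = 12.0,
    fs: float = 100.0,
    bgl_range: tuple[float, float] = DEFAULT_BGL_RANGE,
    seed: int | np.random.SeedSequence = 0,
):
    """Generate per-client feature datasets for federated training.

    Runs the package's own segmentation and feature-extraction path on
    each generated record (one feature row per record) and packages the
    result as :class:`~ppglucose.fl.ClientDataset` triples
    (features, BGL, class). See :func:`generate_client_records` for the
    heterogeneity semantics.
    """
    from .features import FEATURE_NAMES, extract_from_record
    from .fl import ClientDataset

    if effect is None:
        effect = GlucoseEffectSpec()
    per_client = generate_client_records(
        n_clients,
        records_per_client,
        beat=beat,
        noise=noise,
        effect=effect,
        heterogeneity=heterogeneity,
        duration=duration,
        fs=fs,
        bgl_range=bgl_range,
        seed=seed,
    )
    datasets = []
    for i, records in enumerate(per_client):
        rows, bgls, classes = [], [], []
        for rec in records:
            vec = extract_from_record(rec.signal)
            if np.all(np.isnan(vec.values)):
                continue
            rows.append(vec.values)
            bgls.append(rec.bgl)
            classes.append(CLASS_NAMES.index(rec.glucose_class))
        datasets.append(
            ClientDataset(
                features=np.asarray(rows, dtype=float),
                bgl=np.asarray(bgls, dtype=float),
                classes=np.asarray(classes, dtype=int),
                client_id=f"client{i}",
                feature_names=tuple(FEATURE_NAMES),
            )
        )
    return datasets


def planted_feature_matrix(
    n: int,
    d: int = 10,
    informative: tuple[int, ...] = (0, 1, 2),
    noise_sd: float = 0.5,
    bgl_range: tuple[float, float] = DEFAULT_BGL_RANGE,
    seed: int | np.random.SeedSequence = 0,
    thresholds: tuple[float, float] = DEFAULT_CLASS_THRESHOLDS,
):
    """Feature matrix with a planted glucose signal, for selector tests.

    Every column is standard normal; the BGL is an affine function of
    the *sum* of the informative columns plus N(0, noise_sd) residual
    noise, so each informative feature carries an independent additive
    share of the glucose signal and all of them are needed for full
    predictive accuracy (they are complementary, not redundant). The
    remaining columns are pure noise. Returns a DataFrame with columns
    ``f0..f{d-1}``, ``bgl_mgdl`` and ``class``.
    """
    import pandas as pd

    if any(j < 0 or j >= d for j in informative):
        raise ValueError("informative indices must lie in [0, d)")
    if not informative:
        raise ValueError("need at least one informative feature")
    rng = np.random.default_rng(seed)
    lo, hi = bgl_range
    X = rng.standard_normal((n, d))
    score = X[:, list(informative)].sum(axis=1) / np.sqrt(len(informative))
    score = score + noise_sd * rng.standard_normal(n)
    center, spread = (lo + hi) / 2.0, (hi - lo) / 4.0
    bgl = np.clip(center + spread * score, 40.0, 400.0)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(d)])
    df["bgl_mgdl"] = bgl
    df["class"] = [label_class(b, thresholds) for b in bgl]
    return df
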