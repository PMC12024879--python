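"""End-to-end orchestration: simulate -> denoise -> segment/features ->
select -> federated training -> evaluation.

One :class:`PipelineConfig` (optionally loaded from a YAML file) drives
every stage from a single global seed; :func:`run_pipeline` executes the
stages, writes all artifacts (feature tables, selection mask, model,
history, evaluation report) into an output directory and returns a
:class:`RunManifest` recording per-stage record counts and wall-clock
times. A failing stage leaves the manifest with the stages completed so
far and the name of the one that failed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acbs, features, fl, io as pio, metrics, pso, synth, wavelet

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter in one place, driven by a single seed."""

    # simulate
    n_clients: int = 5
    records_per_client: int = 100
    duration_s: float = 12.0
    fs_hz: float = 100.0
    heart_rate_bpm: float = 75.0
    hr_jitter_sd_s: float = 0.02
    white_sd: float = 0.05
    drift_amp: float = 0.30
    artifact_rate_per_min: float = 2.0
    heterogeneity: float = 0.5
    bgl_range: tuple[float, float] = synth.DEFAULT_BGL_RANGE
    effect: synth.GlucoseEffectSpec = field(default_factory=synth.GlucoseEffectSpec)
    test_fraction: float = 0.25
    # denoise
    wavelet_family: str = "mexican_hat"
    scale_f_min: float = 0.5
    scale_f_max: float = 8.0
    n_scales: int = 32
    drift_cutoff_hz: float = 0.5
    # segment
    Lg: int = 100
    min_hr: float = 40.0
    max_hr: float = 180.0
    # select
    pso_enabled: bool = True
    pso: pso.PSOConfig = field(default_factory=pso.PSOConfig)
    pso_mode: str = "acc"
    # train
    fl: fl.FLConfig = field(default_factory=fl.FLConfig)
    # global
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.n_clients < 1 or self.records_per_client < 1:
            raise ValueError("need at least one client and one record per client")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "effect" in raw and isinstance(raw["effect"], dict):
            eff = raw["effect"]
            raw["effect"] = synth.GlucoseEffectSpec(
                affected_features=tuple(eff.get("affected_features", ())),
                effect_slopes=tuple(eff.get("effect_slopes", ())),
                informative_count=int(eff.get("informative_count", 0)),
            )
        if "pso" in raw and isinstance(raw["pso"], dict):
            raw["pso"] = pso.PSOConfig(**raw["pso"])
        if "fl" in raw and isinstance(raw["fl"], dict):
            raw["fl"] = fl.FLConfig(**raw["fl"])
        if "bgl_range" in raw:
            raw["bgl_range"] = tuple(raw["bgl_range"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Copy with the global seed (and the stage seeds derived from
        it) replaced."""
        return replace(
            self,
            seed=seed,
            pso=dataclasses.replace(self.pso, seed=seed + 1),
            fl=dataclasses.replace(self.fl, seed=seed + 2),
        )


@dataclass
class RunManifest:
    """Stage-by-stage accounting of one pipeline run."""

    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, name: str, n_in: int, n_out: int, seconds: float) -> None:
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out), "seconds": round(seconds, 3)}
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


class _Stage:
    def __init__(self, manifest: RunManifest, name: str, n_in: int):
        self.manifest, self.name, self.n_in = manifest, name, n_in
        self.n_out = n_in

    def __enter__(self):
        self.start = time.perf_counter()
        logger.info("stage %s: %d records in", self.name, self.n_in)
        return self

    def __exit__(self, exc_type, exc, tb):
        seconds = time.perf_counter() - self.start
        if exc_type is not None:
            self.manifest.failed_stage = self.name
            self.manifest.record(self.name, self.n_in, 0, seconds)
            return False
        self.manifest.record(self.name, self.n_in, self.n_out, seconds)
        logger.info("stage %s: %d records out (%.2f s)", self.name, self.n_out, seconds)
        return True


def _features_for(records, signals, cfg: PipelineConfig) -> pd.DataFrame:
    return features.build_feature_matrix(
        signals,
        bgl=[r.bgl for r in records],
        glucose_class=[r.glucose_class for r in records],
        Lg=cfg.Lg,
        min_hr=cfg.min_hr,
        max_hr=cfg.max_hr,
    )


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts to
    ``cfg.out_dir``. Fully reproducible from ``cfg.seed``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed)
    try:
        _run_stages(cfg, out, manifest)
    finally:
        manifest.outputs["manifest"] = str(manifest.to_json(out / "manifest.json"))
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    beat = synth.BeatModel(heart_rate=cfg.heart_rate_bpm, hr_jitter_sd=cfg.hr_jitter_sd_s)
    noise = synth.NoiseModel(
        white_sd=cfg.white_sd, drift_amp=cfg.drift_amp, artifact_rate=cfg.artifact_rate_per_min
    )
    n_total = cfg.n_clients * cfg.records_per_client

    with _Stage(manifest, "simulate", n_total) as st:
        per_client = synth.generate_client_records(
            cfg.n_clients,
            [cfg.records_per_client] * cfg.n_clients,
            beat=beat,
            noise=noise,
            effect=cfg.effect,
            heterogeneity=cfg.heterogeneity,
            duration=cfg.duration_s,
            fs=cfg.fs_hz,
            bgl_range=cfg.bgl_range,
            seed=cfg.seed,
        )
        st.n_out = sum(len(c) for c in per_client)

    spec = wavelet.WaveletSpec(family=cfg.wavelet_family)
    grid = wavelet.ScaleGrid.log_spaced(spec, cfg.scale_f_min, cfg.scale_f_max, cfg.n_scales)
    with _Stage(manifest, "denoise", n_total) as st:
        denoised = [
            [wavelet.denoise(r.signal, spec, grid, cfg.drift_cutoff_hz) for r in client]
            for client in per_client
        ]
        st.n_out = sum(len(c) for c in denoised)

    n_test = max(1, int(round(cfg.test_fraction * cfg.records_per_client)))
    with _Stage(manifest, "features", n_total) as st:
        train_frames, test_frames = [], []
        for ci, (client, client_signals) in enumerate(zip(per_client, denoised)):
            df = _features_for(client, client_signals, cfg)
            df["client_id"] = f"client{ci}"
            test_frames.append(df.iloc[len(df) - min(n_test, len(df) - 1) :])
            train_frames.append(df.iloc[: len(df) - min(n_test, len(df) - 1)])
        train_df = pd.concat(train_frames, ignore_index=True)
        test_df = pd.concat(test_frames, ignore_index=True)
        st.n_out = len(train_df) + len(test_df)
        pio.write_features_csv(out / "features_train.csv", train_df)
        pio.write_features_csv(out / "features_test.csv", test_df)
        manifest.outputs["features_train"] = str(out / "features_train.csv")
        manifest.outputs["features_test"] = str(out / "features_test.csv")

    feature_cols = list(features.FEATURE_NAMES)
    with _Stage(manifest, "select", len(train_df)) as st:
        if cfg.pso_enabled:
            swarm = pso.run(
                train_df[feature_cols + ["bgl_mgdl", "class"]], cfg.pso, mode=cfg.pso_mode
            )
            mask = swarm.gbest
            pio.write_mask_json(out / "mask.json", mask, feature_cols, swarm.gbest_fitness)
        else:
            mask = pso.FeatureMask(bits=np.ones(len(feature_cols), dtype=int))
            pio.write_mask_json(out / "mask.json", mask, feature_cols)
        manifest.outputs["mask"] = str(out / "mask.json")
        st.n_out = mask.n_selected

    with _Stage(manifest, "fedtrain", len(train_df)) as st:
        fl_cfg = replace(cfg.fl, n_clients=cfg.n_clients)
        model = fl.FederatedGlucoseModel.from_dataframe(
            train_df, config=fl_cfg, mask=mask, client_col="client_id"
        )
        results = model.fit()
        pio.write_model_json(
            out / "model.json",
            results.params,
            results.scaler,
            fl_cfg,
            feature_names=mask.selected_names(feature_cols),
        )
        results.history_frame.to_csv(out / "history.csv", index=False)
        manifest.outputs["model"] = str(out / "model.json")
        manifest.outputs["history"] = str(out / "history.csv")
        st.n_out = len(results.history)

    with _Stage(manifest, "evaluate", len(test_df)) as st:
        X_test = test_df[feature_cols].to_numpy(dtype=float)[:, mask.bits.astype(bool)]
        report = results.evaluate(
            X_test, test_df["bgl_mgdl"].to_numpy(), test_df["class"].to_numpy()
        )
        report["n_test"] = len(test_df)
        report["n_train"] = len(train_df)
        report["selected_features"] = mask.selected_names(feature_cols)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        manifest.outputs["report"] = str(out / "report.json")
        st.n_out = len(test_df)
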