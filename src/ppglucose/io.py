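"""Plain-text I/O for every artifact the pipeline exchanges.

Formats (all line-oriented text, lossless to 17 significant digits):

signal CSV
    ``# fs=<Hz>`` and ``# t0=<s>`` comment headers, then
    ``time_s,amplitude`` rows. A JSON sidecar with the same stem
    carries record metadata (fs, bgl, class, beat times, subject id).
feature CSV
    header of feature names plus optional ``bgl_mgdl``/``class`` label
    columns; one record per row.
mask JSON
    feature names with selected/not-selected flags plus the raw bit
    vector, mirroring how selection tables are usually reported.
model JSON
    architecture descriptor, flat weight vector and standardization
    statistics — everything needed to reload and run the global model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PPGSignal
from .fl import FLConfig, TargetScaler
from .nn import Architecture, ModelParams
from .pso import FeatureMask

__all__ = [
    "SchemaError",
    "write_signal_csv",
    "read_signal_csv",
    "write_record",
    "read_record_metadata",
    "write_features_csv",
    "read_features_csv",
    "write_mask_json",
    "read_mask_json",
    "write_model_json",
    "read_model_json",
]

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """An artifact violates its documented schema."""


def write_signal_csv(path: str | Path, signal: PPGSignal) -> Path:
    path = Path(path)
    times = signal.times
    with path.open("w") as fh:
        fh.write(f"# fs={signal.fs!r}\n# t0={signal.t0!r}\n")
        fh.write("time_s,amplitude\n")
        for t, v in zip(times, signal.samples):
            fh.write(f"{t:.17g},{v:.17g}\n")
    return path


def read_signal_csv(path: str | Path) -> PPGSignal:
    """Read a signal CSV; the ``# fs=`` header is mandatory."""
    path = Path(path)
    fs = t0 = None
    samples = []
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key == "fs":
                    fs = float(value)
                elif key == "t0":
                    t0 = float(value)
                continue
            if not header_seen:
                if line != "time_s,amplitude":
                    raise SchemaError(f"{path}:{lineno}: expected 'time_s,amplitude' header")
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise SchemaError(f"{path}:{lineno}: expected two columns")
            try:
                value = float(fields[1])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric amplitude") from exc
            if not np.isfinite(value):
                raise SchemaError(f"{path}:{lineno}: non-finite amplitude")
            samples.append(value)
    if fs is None:
        raise SchemaError(f"{path}: missing '# fs=' metadata header")
    return PPGSignal(samples=np.asarray(samples), fs=fs, t0=t0 or 0.0)


def write_record(directory: str | Path, record, stem: str | None = None) -> tuple[Path, Path]:
    """Write a synthetic record as signal CSV + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or record.subject_id
    csv_path = write_signal_csv(directory / f"{stem}.csv", record.signal)
    sidecar = {
        "fs": record.signal.fs,
        "bgl_mgdl": record.bgl,
        "class": record.glucose_class,
        "beat_times_s": np.asarray(record.beat_times).tolist(),
        "subject_id": record.subject_id,
    }
    json_path = directory / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_record_metadata(csv_path: str | Path) -> dict | None:
    """Sidecar metadata for a signal CSV, if present."""
    sidecar = Path(csv_path).with_suffix(".json")
    if not sidecar.exists():
        return None
    return json.loads(sidecar.read_text())


def write_features_csv(path: str | Path, features: pd.DataFrame) -> Path:
    path = Path(path)
    features.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty feature matrix")
    return df


def write_mask_json(path: str | Path, mask: FeatureMask, names, fitness: float | None = None) -> Path:
    names = list(names)
    if len(names) != len(mask):
        raise ValueError("feature names do not match mask length")
    payload = {
        "features": [
            {"name": n, "selected": bool(b)} for n, b in zip(names, mask.bits)
        ],
        "bits": mask.bits.tolist(),
    }
    if fitness is not None:
        payload["fitness"] = fitness
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_mask_json(path: str | Path) -> tuple[FeatureMask, list[str]]:
    payload = json.loads(Path(path).read_text())
    try:
        names = [f["name"] for f in payload["features"]]
        bits = np.asarray(payload["bits"], dtype=int)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed mask JSON") from exc
    return FeatureMask(bits=bits), names


def write_model_json(
    path: str | Path,
    params: ModelParams,
    scaler: TargetScaler | None = None,
    config: FLConfig | None = None,
    feature_names=None,
) -> Path:
    arch = params.arch
    payload: dict = {
        "architecture": {
            "kind": arch.kind,
            "input_dim": arch.input_dim,
            "hidden_units": arch.hidden_units,
            "n_layers": arch.n_layers,
            "n_classes": arch.n_classes,
            "seq_len": arch.seq_len,
        },
        "weights": params.vector.tolist(),
    }
    if scaler is not None:
        payload["scaler"] = {
            "x_mean": np.asarray(scaler.x_mean).tolist(),
            "x_sd": np.asarray(scaler.x_sd).tolist(),
            "y_mean": scaler.y_mean,
            "y_sd": scaler.y_sd,
        }
    if config is not None:
        payload["config"] = {k: getattr(config, k) for k in FLConfig.__dataclass_fields__}
    if feature_names is not None:
        payload["feature_names"] = list(feature_names)
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def read_model_json(path: str | Path) -> tuple[ModelParams, TargetScaler | None]:
    payload = json.loads(Path(path).read_text())
    try:
        arch = Architecture(**payload["architecture"])
        params = ModelParams(vector=np.asarray(payload["weights"], dtype=float), arch=arch)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed model JSON") from exc
    scaler = None
    if "scaler" in payload:
        s = payload["scaler"]
        scaler = TargetScaler(
            x_mean=np.asarray(s["x_mean"], dtype=float),
            x_sd=np.asarray(s["x_sd"], dtype=float),
            y_mean=float(s["y_mean"]),
            y_sd=float(s["y_sd"]),
        )
    return params, scaler
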