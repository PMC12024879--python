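"""Federated multi-task training of the glucose model.

Simulates FedAvg across K clients (e.g. healthcare institutions), each
holding a private table of PPG feature vectors with reference BGLs and
glucose classes. Every round the server broadcasts the global
parameter vector, each client runs a few epochs of mini-batch
optimization of the joint loss Lt = lambda1 * MSE + lambda2 * CCE on
its own data, and the server aggregates the returned parameter vectors
weighted by client size:

    Mp <- sum_i (N_i / N) Mp_i .

Only parameter vectors (or their deltas) ever cross the client
boundary — the aggregation functions accept nothing else by
construction. Standardization statistics for features and targets are
scalar metadata computed once from the pooled training targets and
shipped with the model.

The user-facing surface follows the Model/Results convention:
:class:`FederatedGlucoseModel` is built from client datasets and a
config, ``fit()`` returns a :class:`FederatedResults` carrying the
trained parameters, the per-round loss history, ``predict()``,
``evaluate()`` and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from . import nn
from .nn import Architecture, ModelParams

__all__ = [
    "ClientDataset",
    "FLConfig",
    "LossReport",
    "TargetScaler",
    "multitask_loss",
    "local_train",
    "delta",
    "fedavg",
    "train_federated",
    "train_centralized",
    "predict",
    "FederatedGlucoseModel",
    "FederatedResults",
]

CLASS_NAMES = ("hypo", "normo", "hyper")


@dataclass(frozen=True)
class ClientDataset:
    """One client's private training table.

    features is (N, d); bgl is the reference glucose in mg/dL; classes
    are integer labels indexing CLASS_NAMES.
    """

    features: np.ndarray
    bgl: np.ndarray
    classes: np.ndarray
    client_id: str = "client"
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim not in (2, 3):  # (n, d) rows or (n, seq, d) sequences
            raise ValueError(f"features must be 2-D or 3-D, got shape {X.shape}")
        y = np.asarray(self.bgl, dtype=float)
        c = np.asarray(self.classes, dtype=int)
        if X.shape[0] != y.size or y.size != c.size:
            raise ValueError("features, bgl and classes must have equal row counts")
        if y.size < 1:
            raise ValueError("client dataset must hold at least one record")
        if c.min() < 0 or c.max() >= len(CLASS_NAMES):
            raise ValueError("class labels must index hypo/normo/hyper")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "bgl", y)
        object.__setattr__(self, "classes", c)

    @property
    def size(self) -> int:
        return self.bgl.size

    @property
    def onehot(self) -> np.ndarray:
        out = np.zeros((self.size, len(CLASS_NAMES)))
        out[np.arange(self.size), self.classes] = 1.0
        return out

    def select(self, bits: np.ndarray) -> "ClientDataset":
        """Restrict to the features a selection mask keeps."""
        cols = np.flatnonzero(np.asarray(bits).astype(int))
        names = (
            tuple(np.asarray(self.feature_names)[cols]) if self.feature_names is not None else None
        )
        return replace(self, features=self.features[..., cols], feature_names=names)


@dataclass(frozen=True)
class FLConfig:
    """Federation and local-model hyper-parameters.

    Defaults mirror a 5-client simulation trained for 20 global rounds
    with Adam at learning rate 0.001, batch size 32 and dropout 0.3.
    lambda_reg/lambda_cls weight the regression and classification
    tasks and must not both be zero.
    """

    n_clients: int | None = 5
    rounds: int = 20
    local_epochs: int = 1
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    lambda_reg: float = 1.0
    lambda_cls: float = 1.0
    dropout: float = 0.3
    hidden_units: int = 64
    n_layers: int = 2
    model_kind: str = "mlp"
    seq_len: int = 5
    seed: int = 0
    standardize_features: bool = True
    standardize_targets: bool = True

    def __post_init__(self) -> None:
        if self.n_clients is not None and self.n_clients < 1:
            raise ValueError("n_clients must be >= 1")
        if self.rounds < 0 or self.local_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid rounds/local_epochs/batch_size")
        if not (self.learning_rate >= 0):
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.lambda_reg < 0 or self.lambda_cls < 0:
            raise ValueError("task weights must be non-negative")
        if self.lambda_reg == 0 and self.lambda_cls == 0:
            raise ValueError("at least one task weight must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.model_kind not in ("mlp", "recurrent"):
            raise ValueError("model_kind must be 'mlp' or 'recurrent'")


@dataclass(frozen=True)
class LossReport:
    """Joint loss decomposition: Lr (regression MSE, target-scale
    units), Lc (cross-entropy, nats), Lt = lambda1*Lr + lambda2*Lc."""

    Lr: float
    Lc: float
    Lt: float


@dataclass(frozen=True)
class TargetScaler:
    """Feature/target standardization statistics (shared metadata)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    @classmethod
    def fit(cls, clients: list[ClientDataset], cfg: FLConfig) -> "TargetScaler":
        X = np.vstack([c.features for c in clients])
        y = np.concatenate([c.bgl for c in clients])
        d = X.shape[-1]
        if cfg.standardize_features:
            x_mean = X.reshape(-1, d).mean(axis=0)
            x_sd = X.reshape(-1, d).std(axis=0)
            x_sd = np.where(x_sd > 0, x_sd, 1.0)
        else:
            x_mean, x_sd = np.zeros(d), np.ones(d)
        if cfg.standardize_targets:
            y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
        else:
            y_mean, y_sd = 0.0, 1.0
        return cls(x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd)

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_sd

    def inverse_y(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_sd + self.y_mean

    @classmethod
    def identity(cls, d: int) -> "TargetScaler":
        return cls(x_mean=np.zeros(d), x_sd=np.ones(d), y_mean=0.0, y_sd=1.0)


def multitask_loss(
    pred_bgl: np.ndarray,
    true_bgl: np.ndarray,
    pred_probs: np.ndarray,
    true_onehot: np.ndarray,
    lambda_reg: float = 1.0,
    lambda_cls: float = 1.0,
) -> LossReport:
    """Joint regression + classification loss on given predictions.

    Lr = mean (pred - true)^2 (mg/dL^2 when inputs are in mg/dL);
    Lc = categorical cross-entropy in nats, with zero probabilities for
    a true class clipped at 1e-12 (a warning is raised since that
    signals a saturated classifier); Lt = lambda1*Lr + lambda2*Lc.
    """
    pred_bgl = np.asarray(pred_bgl, dtype=float)
    true_bgl = np.asarray(true_bgl, dtype=float)
    probs = np.asarray(pred_probs, dtype=float)
    onehot = np.asarray(true_onehot, dtype=float)
    if pred_bgl.shape != true_bgl.shape or probs.shape != onehot.shape:
        raise ValueError("prediction/target shapes disagree")
    if probs.ndim != 2 or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pred_probs rows must sum to 1")
    lr = float(np.mean((pred_bgl - true_bgl) ** 2))
    true_p = np.sum(probs * onehot, axis=1)
    if np.any(true_p <= 0):
        warnings.warn("zero predicted probability for a true class; clipping at 1e-12", stacklevel=2)
    lc = float(-np.mean(np.log(np.clip(true_p, 1e-12, None))))
    return LossReport(Lr=lr, Lc=lc, Lt=lambda_reg * lr + lambda_cls * lc)


def _architecture(cfg: FLConfig, input_dim: int) -> Architecture:
    return Architecture(
        kind=cfg.model_kind,
        input_dim=input_dim,
        hidden_units=cfg.hidden_units,
        n_layers=cfg.n_layers,
        seq_len=cfg.seq_len if cfg.model_kind == "recurrent" else None,
    )


def _prepare(data: ClientDataset, scaler: TargetScaler) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = scaler.transform_x(data.features)
    y = scaler.transform_y(data.bgl)
    return X, y, data.onehot


def local_train(
    params: ModelParams,
    data: ClientDataset,
    cfg: FLConfig,
    seed: int | np.random.SeedSequence | None = None,
    scaler: TargetScaler | None = None,
) -> ModelParams:
    """One client's local update: ``local_epochs`` passes of shuffled
    mini-batch optimization of the joint loss, starting from the
    broadcast parameters. A fresh optimizer is used per call (FedAvg
    shares parameters, not optimizer state). Deterministic given the
    seed; aborts on a non-finite loss.
    """
    if scaler is None:
        scaler = TargetScaler.identity(params.arch.input_dim)
    X, y, onehot = _prepare(data, scaler)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    opt = nn.make_optimizer(cfg.optimizer, cfg.learning_rate)
    vec = params.vector.copy()
    n = data.size
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grad = nn.loss_and_grad(
                ModelParams(vec, params.arch),
                X[idx],
                y[idx],
                onehot[idx],
                lambda_reg=cfg.lambda_reg,
                lambda_cls=cfg.lambda_cls,
                dropout=cfg.dropout,
                rng=rng,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss on client {data.client_id!r} "
                    f"(batch of {idx.size}, lr={cfg.learning_rate})"
                )
            vec = opt.step(vec, grad)
    return ModelParams(vec, params.arch)


def delta(before: ModelParams, after: ModelParams) -> ModelParams:
    """Parameter update after - before (what a client would transmit)."""
    if before.arch != after.arch:
        raise ValueError("parameter architectures disagree")
    return ModelParams(after.vector - before.vector, before.arch)


def fedavg(client_params: list[ModelParams], sizes: list[int]) -> ModelParams:
    """Size-weighted federated average of client parameter vectors."""
    if not client_params:
        raise ValueError("no client parameters to aggregate")
    if len(client_params) != len(sizes):
        raise ValueError("one size per client parameter vector required")
    if any(s <= 0 for s in sizes):
        raise ValueError("client sizes must be positive")
    arch = client_params[0].arch
    if any(p.arch != arch for p in client_params):
        raise ValueError("all clients must share one architecture")
    weights = np.asarray(sizes, dtype=float)
    weights /= weights.sum()
    vec = np.zeros_like(client_params[0].vector)
    for w, p in zip(weights, client_params):
        vec += w * p.vector
    return ModelParams(vec, arch)


def _global_loss(
    params: ModelParams, clients: list[ClientDataset], cfg: FLConfig, scaler: TargetScaler
) -> LossReport:
    """Size-weighted training loss of the global model (inference mode)."""
    total = np.array([0.0, 0.0, 0.0])
    n_total = sum(c.size for c in clients)
    for c in clients:
        X, y, onehot = _prepare(c, scaler)
        reg, probs = nn.predict_raw(params, X)
        lt, lr, lc = nn.multitask_loss_values(reg, probs, y, onehot, cfg.lambda_reg, cfg.lambda_cls)
        total += (c.size / n_total) * np.array([lt, lr, lc])
    return LossReport(Lr=float(total[1]), Lc=float(total[2]), Lt=float(total[0]))


def train_federated(
    clients: list[ClientDataset],
    cfg: FLConfig | None = None,
    scaler: TargetScaler | None = None,
) -> tuple[ModelParams, list[dict], TargetScaler]:
    """Run the full federation and return (global params, history, scaler).

    Each round: broadcast -> local_train on every client -> FedAvg.
    The history holds one entry per round with the size-weighted
    training losses of the aggregated global model. Reproducible from
    cfg.seed (per-round, per-client seeds are spawned from it).
    """
    cfg = cfg or FLConfig()
    if not clients:
        raise ValueError("need at least one client")
    if cfg.n_clients is not None and cfg.n_clients != len(clients):
        raise ValueError(f"config says {cfg.n_clients} clients, got {len(clients)}")
    d = clients[0].features.shape[-1]
    if any(c.features.shape[-1] != d for c in clients):
        raise ValueError("clients disagree on feature dimension")
    arch = _architecture(cfg, d)
    if scaler is None:
        scaler = TargetScaler.fit(clients, cfg)
    root = np.random.SeedSequence(cfg.seed)
    init_ss, *round_ss = root.spawn(1 + max(cfg.rounds, 0))
    params = ModelParams.init(arch, np.random.default_rng(init_ss))
    history: list[dict] = []
    sizes = [c.size for c in clients]
    for rnd in range(cfg.rounds):
        client_seeds = round_ss[rnd].spawn(len(clients))
        updated = []
        for c, s in zip(clients, client_seeds):
            try:
                updated.append(local_train(params, c, cfg, seed=s, scaler=scaler))
            except Exception as exc:
                raise RuntimeError(f"round {rnd}: client {c.client_id!r} failed") from exc
        params = fedavg(updated, sizes)
        report = _global_loss(params, clients, cfg, scaler)
        history.append(
            {"round": rnd, "Lt": report.Lt, "Lr": report.Lr, "Lc": report.Lc,
             "rmse_mgdl": float(np.sqrt(report.Lr)) * (scaler.y_sd or 1.0)}
        )
    return params, history, scaler


def train_centralized(
    data: ClientDataset, cfg: FLConfig, scaler: TargetScaler | None = None
) -> ModelParams:
    """Pooled-data training: the degenerate single-client federation.

    Implemented as exactly that — ``rounds`` sequential local updates —
    so a one-client federation and centralized training coincide
    bit-for-bit at the same seed.
    """
    cfg = replace(cfg, n_clients=1)
    params, _, _ = train_federated([data], cfg, scaler=scaler)
    return params


def predict(
    params: ModelParams,
    features: np.ndarray,
    scaler: TargetScaler | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inference with the global model.

    Returns (bgl_pred in mg/dL, class index into CLASS_NAMES, class
    probabilities). Deterministic: dropout is disabled.
    """
    if scaler is None:
        scaler = TargetScaler.identity(params.arch.input_dim)
    X = scaler.transform_x(np.asarray(features, dtype=float))
    reg, probs = nn.predict_raw(params, X)
    return scaler.inverse_y(reg), probs.argmax(axis=1), probs


class FederatedGlucoseModel:
    """Federated multi-task glucose model over client feature tables.

    Parameters
    ----------
    clients : list of ClientDataset
        Private per-institution tables (features, BGL, class).
    config : FLConfig, optional
        Training configuration; defaults to the 5-client setup.
    mask : array-like of 0/1, optional
        Feature-selection mask (e.g. a BPSO result) applied to every
        client before training.
    """

    def __init__(self, clients, config: FLConfig | None = None, mask=None):
        config = config or FLConfig(n_clients=len(clients))
        if config.n_clients is None:
            config = replace(config, n_clients=len(clients))
        if mask is not None:
            bits = getattr(mask, "bits", mask)
            clients = [c.select(bits) for c in clients]
            self.mask = np.asarray(bits).astype(int)
        else:
            self.mask = None
        self.clients = list(clients)
        self.config = config
        self.feature_names = self.clients[0].feature_names

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_clients: int = 5,
        config: FLConfig | None = None,
        mask=None,
        client_col: str | None = None,
    ) -> "FederatedGlucoseModel":
        """Build from a labelled feature matrix.

        Rows are assigned to clients by ``client_col`` when given,
        otherwise split into ``n_clients`` contiguous shards.
        """
        feature_cols = [c for c in df.columns if c not in ("bgl_mgdl", "class", client_col)]
        if "bgl_mgdl" not in df.columns or "class" not in df.columns:
            raise ValueError("dataframe needs 'bgl_mgdl' and 'class' columns")
        classes = df["class"].map(lambda c: CLASS_NAMES.index(c)).to_numpy()
        if client_col is not None:
            groups = [g for _, g in df.groupby(client_col, sort=True)]
        else:
            groups = [df.iloc[idx] for idx in np.array_split(np.arange(len(df)), n_clients)]
        clients = []
        for i, g in enumerate(groups):
            idx = g.index
            clients.append(
                ClientDataset(
                    features=g[feature_cols].to_numpy(dtype=float),
                    bgl=g["bgl_mgdl"].to_numpy(dtype=float),
                    classes=classes[df.index.get_indexer(idx)],
                    client_id=f"client{i}",
                    feature_names=tuple(feature_cols),
                )
            )
        cfg = config or FLConfig(n_clients=len(clients))
        return cls(clients, cfg, mask=mask)

    def fit(self) -> "FederatedResults":
        params, history, scaler = train_federated(self.clients, self.config)
        return FederatedResults(self, params, history, scaler)


class FederatedResults:
    """Fitted global model: parameters, training history, inference."""

    def __init__(self, model: FederatedGlucoseModel, params: ModelParams, history, scaler):
        self.model = model
        self.params = params
        self.history = history
        self.scaler = scaler

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def predict(self, features: np.ndarray) -> pd.DataFrame:
        """Predicted BGL (mg/dL) and glucose class for each row."""
        bgl, cls_idx, probs = predict(self.params, features, self.scaler)
        return pd.DataFrame(
            {
                "bgl_pred_mgdl": bgl,
                "class_pred": [CLASS_NAMES[i] for i in cls_idx],
                **{f"p_{name}": probs[:, i] for i, name in enumerate(CLASS_NAMES)},
            }
        )

    def evaluate(self, features: np.ndarray, bgl: np.ndarray, classes: np.ndarray | None = None):
        """Regression metrics + Clarke zone percentages on a test set."""
        pred = self.predict(features)
        out = metrics_mod.regression_metrics(
            metrics_mod.PairedReadings(reference=np.asarray(bgl, dtype=float),
                                       predicted=pred["bgl_pred_mgdl"].to_numpy())
        )
        ceg = metrics_mod.ceg_report(
            metrics_mod.PairedReadings(reference=np.asarray(bgl, dtype=float),
                                       predicted=pred["bgl_pred_mgdl"].to_numpy())
        )
        out = dict(out)
        out.update({f"ceg_{z}_pct": ceg.percentages[z] for z in "ABCDE"})
        if classes is not None:
            classes = np.asarray(classes)
            if classes.dtype.kind in "UO":
                classes = np.array([CLASS_NAMES.index(c) for c in classes])
            pred_idx = np.array([CLASS_NAMES.index(c) for c in pred["class_pred"]])
            out["class_accuracy_pct"] = float(100.0 * np.mean(pred_idx == classes))
        return out

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels."""
        cfg = self.model.config
        lines = [
            "Federated glucose model",
            "=" * 58,
            f"clients: {len(self.model.clients):>4}    rounds: {cfg.rounds:>4}    "
            f"local epochs: {cfg.local_epochs}",
            f"model: {cfg.model_kind} ({cfg.n_layers} x {cfg.hidden_units}), "
            f"dropout {cfg.dropout}, optimizer {cfg.optimizer} @ lr {cfg.learning_rate}",
            f"task weights: lambda_reg={cfg.lambda_reg}, lambda_cls={cfg.lambda_cls}",
            f"parameters: {self.params.arch.n_params}",
            "-" * 58,
        ]
        for c in self.model.clients:
            lines.append(f"  {c.client_id:<12} n = {c.size}")
        if self.history:
            first, last = self.history[0], self.history[-1]
            lines += [
                "-" * 58,
                f"train Lt: {first['Lt']:.4f} (round 0) -> {last['Lt']:.4f} "
                f"(round {last['round']})",
                f"train RMSE: {last['rmse_mgdl']:.2f} mg/dL",
            ]
        if self.model.mask is not None:
            lines.append(f"feature mask: {''.join(map(str, self.model.mask))}")
        return "\n".join(lines)
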