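"""Small numpy neural networks for multi-task glucose modelling.

Two architectures share a common two-headed output: a linear regression
head (continuous BGL) and a 3-way softmax classification head
(hypo/normo/hyperglycemia):

``mlp``
    input -> [dense + ReLU + dropout] x n_layers -> heads. With
    n_layers = 0 both heads act directly on the input features, which
    gives a plain (multi-task) linear model — handy because its
    gradient step has a closed form.
``recurrent``
    input sequence (N, T, d) -> stacked tanh recurrent layers ->
    dropout on the final hidden state -> heads.

Parameters live in a single flat float64 vector tied to an
:class:`Architecture` descriptor, so federated averaging and parameter
deltas are plain vector arithmetic. Gradients are computed by manual
backpropagation (verified against finite differences in the test
suite); optimizers are SGD and Adam on the flat vector.

The combined training objective is Lt = lambda1 * Lr + lambda2 * Lc
with Lr the mean squared regression error and Lc the categorical
cross-entropy, both means over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Architecture",
    "ModelParams",
    "forward",
    "loss_and_grad",
    "predict_raw",
    "SGD",
    "Adam",
    "make_optimizer",
]

N_CLASSES = 3


@dataclass(frozen=True)
class Architecture:
    """Network shape descriptor.

    seq_len is only meaningful for the recurrent kind; n_layers = 0 is
    only allowed for the MLP (a linear model).
    """

    kind: str = "mlp"
    input_dim: int = 13
    hidden_units: int = 64
    n_layers: int = 2
    n_classes: int = N_CLASSES
    seq_len: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "recurrent"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.kind == "recurrent" and self.n_layers < 1:
            raise ValueError("recurrent model needs at least one layer")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.n_layers > 0 and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")

    def param_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        shapes: list[tuple[str, tuple[int, ...]]] = []
        prev = self.input_dim
        for layer in range(self.n_layers):
            if self.kind == "mlp":
                shapes.append((f"W{layer}", (prev, self.hidden_units)))
            else:
                shapes.append((f"Wx{layer}", (prev, self.hidden_units)))
                shapes.append((f"Wh{layer}", (self.hidden_units, self.hidden_units)))
            shapes.append((f"b{layer}", (self.hidden_units,)))
            prev = self.hidden_units
        shapes.append(("Wr", (prev,)))
        shapes.append(("br", ()))
        shapes.append(("Wc", (prev, self.n_classes)))
        shapes.append(("bc", (self.n_classes,)))
        return shapes

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for _, s in self.param_shapes())


@dataclass(frozen=True)
class ModelParams:
    """Flat parameter vector with its architecture descriptor."""

    vector: np.ndarray
    arch: Architecture

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.ndim != 1 or vec.size != self.arch.n_params:
            raise ValueError(
                f"parameter vector of size {vec.size} does not match the "
                f"architecture ({self.arch.n_params} parameters)"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError("parameters contain non-finite values")
        object.__setattr__(self, "vector", vec)

    @classmethod
    def init(cls, arch: Architecture, rng: np.random.Generator) -> "ModelParams":
        """Glorot-uniform weights, zero biases."""
        parts = []
        for name, shape in arch.param_shapes():
            size = int(np.prod(shape)) if shape else 1
            if name.startswith("W"):
                fan_in = shape[0]
                fan_out = shape[1] if len(shape) > 1 else 1
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                parts.append(rng.uniform(-limit, limit, size=size))
            else:
                parts.append(np.zeros(size))
        return cls(vector=np.concatenate(parts), arch=arch)

    def unflatten(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        offset = 0
        for name, shape in self.arch.param_shapes():
            size = int(np.prod(shape)) if shape else 1
            out[name] = self.vector[offset : offset + size].reshape(shape)
            offset += size
        return out

    @staticmethod
    def flatten(parts: dict[str, np.ndarray], arch: Architecture) -> np.ndarray:
        return np.concatenate(
            [np.asarray(parts[name], dtype=float).ravel() for name, _ in arch.param_shapes()]
        )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _dropout_mask(
    shape: tuple[int, ...], rate: float, rng: np.random.Generator | None
) -> np.ndarray | None:
    if rate <= 0 or rng is None:
        return None
    # inverted dropout: scale at train time, identity at inference
    return (rng.uniform(size=shape) >= rate) / (1.0 - rate)


def forward(
    params: ModelParams,
    X: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the network; returns (regression output, class probabilities,
    cache for backprop). Dropout is active only when a rate and an rng
    are both supplied (training mode)."""
    p = params.unflatten()
    arch = params.arch
    X = np.asarray(X, dtype=float)
    cache: dict = {"X": X, "masks": []}
    if arch.kind == "mlp":
        if X.ndim != 2 or X.shape[1] != arch.input_dim:
            raise ValueError(f"expected input (n, {arch.input_dim}), got {X.shape}")
        h = X
        cache["hs"], cache["zs"] = [h], []
        for layer in range(arch.n_layers):
            z = h @ p[f"W{layer}"] + p[f"b{layer}"]
            h = np.maximum(z, 0.0)
            mask = _dropout_mask(h.shape, dropout, rng)
            if mask is not None:
                h = h * mask
            cache["zs"].append(z)
            cache["masks"].append(mask)
            cache["hs"].append(h)
    else:
        if X.ndim != 3 or X.shape[2] != arch.input_dim:
            raise ValueError(f"expected input (n, seq, {arch.input_dim}), got {X.shape}")
        a = X
        cache["layer_inputs"], cache["layer_states"] = [], []
        for layer in range(arch.n_layers):
            n, T, _ = a.shape
            hs = np.zeros((n, T + 1, arch.hidden_units))
            for t in range(T):
                z = a[:, t] @ p[f"Wx{layer}"] + hs[:, t] @ p[f"Wh{layer}"] + p[f"b{layer}"]
                hs[:, t + 1] = np.tanh(z)
            cache["layer_inputs"].append(a)
            cache["layer_states"].append(hs)
            a = hs[:, 1:]
        h = a[:, -1]
        mask = _dropout_mask(h.shape, dropout, rng)
        if mask is not None:
            h = h * mask
        cache["masks"].append(mask)
        cache["h_final"] = h
    reg = h @ p["Wr"] + p["br"]
    probs = _softmax(h @ p["Wc"] + p["bc"])
    cache["h_last"] = h
    cache["probs"] = probs
    cache["reg"] = reg
    return reg, probs, cache


def multitask_loss_values(
    reg: np.ndarray,
    probs: np.ndarray,
    y: np.ndarray,
    onehot: np.ndarray,
    lambda_reg: float,
    lambda_cls: float,
) -> tuple[float, float, float]:
    """(Lt, Lr, Lc) on whatever scale the caller's targets are in."""
    lr = float(np.mean((reg - y) ** 2))
    logp = np.log(np.clip(probs, 1e-12, None))
    lc = float(-np.mean(np.sum(onehot * logp, axis=1)))
    return lambda_reg * lr + lambda_cls * lc, lr, lc


def loss_and_grad(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    onehot: np.ndarray,
    lambda_reg: float = 1.0,
    lambda_cls: float = 1.0,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Combined loss and its gradient as a flat vector."""
    arch = params.arch
    p = params.unflatten()
    reg, probs, cache = forward(params, X, dropout=dropout, rng=rng)
    n = X.shape[0]
    loss, _, _ = multitask_loss_values(reg, probs, y, onehot, lambda_reg, lambda_cls)

    grads: dict[str, np.ndarray] = {}
    dreg = lambda_reg * 2.0 * (reg - y) / n
    dlogits = lambda_cls * (probs - onehot) / n
    h = cache["h_last"]
    grads["Wr"] = h.T @ dreg
    grads["br"] = np.asarray(dreg.sum())
    grads["Wc"] = h.T @ dlogits
    grads["bc"] = dlogits.sum(axis=0)
    dh = np.outer(dreg, p["Wr"]) + dlogits @ p["Wc"].T

    if arch.kind == "mlp":
        for layer in range(arch.n_layers - 1, -1, -1):
            mask = cache["masks"][layer]
            if mask is not None:
                dh = dh * mask
            dz = dh * (cache["zs"][layer] > 0)
            grads[f"W{layer}"] = cache["hs"][layer].T @ dz
            grads[f"b{layer}"] = dz.sum(axis=0)
            dh = dz @ p[f"W{layer}"].T
    else:
        mask = cache["masks"][0]
        if mask is not None:
            dh = dh * mask
        T = X.shape[1]
        # gradient w.r.t. the top layer's output sequence: heads touch
        # only the final step
        dH = np.zeros_like(cache["layer_states"][-1][:, 1:])
        dH[:, -1] = dh
        for layer in range(arch.n_layers - 1, -1, -1):
            a = cache["layer_inputs"][layer]
            hs = cache["layer_states"][layer]
            gWx = np.zeros_like(p[f"Wx{layer}"])
            gWh = np.zeros_like(p[f"Wh{layer}"])
            gb = np.zeros_like(p[f"b{layer}"])
            da = np.zeros_like(a)
            carry = np.zeros((X.shape[0], arch.hidden_units))
            for t in range(T - 1, -1, -1):
                dht = dH[:, t] + carry
                dz = dht * (1.0 - hs[:, t + 1] ** 2)
                gWx += a[:, t].T @ dz
                gWh += hs[:, t].T @ dz
                gb += dz.sum(axis=0)
                da[:, t] = dz @ p[f"Wx{layer}"].T
                carry = dz @ p[f"Wh{layer}"].T
            grads[f"Wx{layer}"] = gWx
            grads[f"Wh{layer}"] = gWh
            grads[f"b{layer}"] = gb
            dH = da
    return loss, ModelParams.flatten(grads, arch)


def predict_raw(params: ModelParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inference pass (dropout disabled): (regression output, probs)."""
    reg, probs, _ = forward(params, X, dropout=0.0, rng=None)
    return reg, probs


class SGD:
    """Plain gradient descent on the flat parameter vector."""

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, vector: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return vector - self.lr * grad


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: np.ndarray | None = None
        self.v: np.ndarray | None = None
        self.t = 0

    def step(self, vector: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(vector)
            self.v = np.zeros_like(vector)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return vector - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def make_optimizer(name: str, lr: float):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ValueError(f"unknown optimizer {name!r}")
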