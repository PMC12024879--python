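"""Binary particle swarm optimization (BPSO) for feature selection.

Each particle carries a bit mask over the feature set. Velocities
evolve by the classic inertia + cognitive + social rule,

    ve <- wt*ve + co1*ra1*(pbest - sb) + co2*ra2*(gbest - sb),

and positions are re-sampled through a sigmoid transfer: bit j is set
when sigmoid(ve_j) exceeds a fresh uniform draw. A mask's fitness is

    Ft = alpha * score(mask) - beta * |mask| / d,

where score is a cross-validated model score in [0, 1] (glucose-class
accuracy by default, or a rescaled negative regression RMSE), so beta
prices each selected feature and alpha weights raw performance. The
empty mask is assigned -inf and can never become a personal or global
best.

Defaults: 30 particles, inertia 0.729, cognitive = social = 1.49,
50 iterations, early stop after 10 non-improving iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMask",
    "Particle",
    "PSOConfig",
    "SwarmResult",
    "fitness",
    "update_velocity",
    "update_position",
    "make_cv_evaluator",
    "run",
]


@dataclass(frozen=True)
class FeatureMask:
    """Binary feature-selection vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits).astype(int)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("mask bits must be a 1-D 0/1 vector")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def selected_names(self, names: list[str] | tuple[str, ...]) -> list[str]:
        if len(names) != len(self.bits):
            raise ValueError("names length does not match mask length")
        return [n for n, b in zip(names, self.bits) if b]


@dataclass
class Particle:
    """Swarm member: current mask, velocity, and personal best."""

    position: np.ndarray
    velocity: np.ndarray
    pbest: np.ndarray
    pbest_fitness: float


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyper-parameters. alpha/beta weight the fitness trade-off
    between model score and mask size; velocity_clamp keeps the sigmoid
    transfer out of saturation."""

    n_particles: int = 30
    inertia: float = 0.729
    cognitive: float = 1.49
    social: float = 1.49
    max_iter: int = 50
    patience: int = 10
    alpha: float = 1.0
    beta: float = 0.1
    seed: int = 0
    velocity_clamp: float = 6.0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not (0 < self.inertia <= 1):
            raise ValueError("inertia must be in (0, 1]")
        if self.cognitive < 0 or self.social < 0:
            raise ValueError("cognitive/social coefficients must be non-negative")
        if self.patience < 1 or self.max_iter < 1:
            raise ValueError("patience and max_iter must be >= 1")
        if self.velocity_clamp <= 0:
            raise ValueError("velocity_clamp must be positive")


@dataclass(frozen=True)
class SwarmResult:
    """Best mask found, its fitness, and the per-iteration best-fitness
    trace (monotone non-decreasing)."""

    gbest: FeatureMask
    gbest_fitness: float
    history: np.ndarray
    n_evaluations: int = 0


def fitness(
    mask: np.ndarray | FeatureMask,
    evaluator: Callable[[np.ndarray], float],
    alpha: float = 1.0,
    beta: float = 0.1,
) -> float:
    """Ft = alpha * score - beta * |mask|/d; empty mask -> -inf."""
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask).astype(int)
    d = bits.size
    if d == 0:
        raise ValueError("mask has zero length")
    k = int(bits.sum())
    if k == 0:
        return -np.inf
    return float(alpha * evaluator(bits) - beta * k / d)


def update_velocity(
    p: Particle,
    gbest: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """New velocity with per-dimension uniform draws, clamped."""
    d = p.velocity.size
    ra1 = rng.uniform(0.0, 1.0, d)
    ra2 = rng.uniform(0.0, 1.0, d)
    ve = (
        cfg.inertia * p.velocity
        + cfg.cognitive * ra1 * (p.pbest - p.position)
        + cfg.social * ra2 * (gbest - p.position)
    )
    return np.clip(ve, -cfg.velocity_clamp, cfg.velocity_clamp)


def sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_position(p: Particle, rng: np.random.Generator) -> np.ndarray:
    """Sample a new bit vector: bit = 1 where sigmoid(ve) > U(0,1)."""
    ra = rng.uniform(0.0, 1.0, p.velocity.size)
    return (sigmoid(p.velocity) > ra).astype(int)


def make_cv_evaluator(
    features: pd.DataFrame,
    mode: str = "acc",
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[Callable[[np.ndarray], float], list[str]]:
    """Cross-validated mask evaluator over a labelled feature matrix.

    ``acc`` mode scores a mask by 5-fold CV accuracy of a standardized
    logistic regression on the ``class`` column; ``rmse`` mode scores
    by 1 - RMSE/SD(bgl) (clipped to [0, 1]) of a ridge regression on
    ``bgl_mgdl``. Returns (evaluator, feature_names).
    """
    from sklearn.linear_model import LogisticRegression, Ridge
    from sklearn.model_selection import KFold, cross_val_predict, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    label_cols = [c for c in ("bgl_mgdl", "class") if c in features.columns]
    names = [c for c in features.columns if c not in label_cols]
    X_full = features[names].to_numpy(dtype=float)
    if mode == "acc":
        if "class" not in features.columns:
            raise ValueError("acc mode needs a 'class' column")
        y = features["class"].to_numpy()
    elif mode == "rmse":
        if "bgl_mgdl" not in features.columns:
            raise ValueError("rmse mode needs a 'bgl_mgdl' column")
        y = features["bgl_mgdl"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown evaluator mode {mode!r}")
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)

    def evaluator(bits: np.ndarray) -> float:
        cols = np.flatnonzero(bits)
        if cols.size == 0:
            return 0.0
        X = X_full[:, cols]
        if mode == "acc":
            model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=300))
            scores = cross_val_score(model, X, y, cv=cv, scoring="accuracy")
            return float(scores.mean())
        model = make_pipeline(StandardScaler(), Ridge(alpha=1.0))
        pred = cross_val_predict(model, X, y, cv=cv)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        return float(np.clip(1.0 - rmse / y.std(), 0.0, 1.0))

    return evaluator, names


def run(
    features: pd.DataFrame | None = None,
    cfg: PSOConfig | None = None,
    evaluator: Callable[[np.ndarray], float] | None = None,
    d: int | None = None,
    mode: str = "acc",
) -> SwarmResult:
    """Run the swarm and return the best mask found.

    Either pass a labelled feature matrix (a default cross-validation
    evaluator is built from it) or an explicit ``evaluator`` plus the
    mask length ``d``. Fully reproducible from ``cfg.seed``; evaluator
    calls are cached per distinct mask.
    """
    cfg = cfg or PSOConfig()
    if evaluator is None:
        if features is None:
            raise ValueError("need a feature matrix or an explicit evaluator")
        evaluator, names = make_cv_evaluator(features, mode=mode, seed=cfg.seed)
        d = len(names)
    if d is None or d < 2:
        raise ValueError("mask length d must be >= 2")

    cache: dict[bytes, float] = {}
    n_evals = 0

    def cached_fitness(bits: np.ndarray) -> float:
        nonlocal n_evals
        key = bits.astype(np.int8).tobytes()
        if key not in cache:
            cache[key] = fitness(bits, evaluator, cfg.alpha, cfg.beta)
            n_evals += 1
        return cache[key]

    rng = np.random.default_rng(cfg.seed)
    positions = rng.integers(0, 2, size=(cfg.n_particles, d))
    velocities = rng.uniform(-1.0, 1.0, size=(cfg.n_particles, d))
    particles = []
    for i in range(cfg.n_particles):
        fit = cached_fitness(positions[i])
        particles.append(
            Particle(
                position=positions[i].copy(),
                velocity=velocities[i],
                pbest=positions[i].copy(),
                pbest_fitness=fit,
            )
        )
    best = max(particles, key=lambda p: p.pbest_fitness)
    gbest = best.pbest.copy()
    gbest_fit = best.pbest_fitness
    if not np.isfinite(gbest_fit):
        # every initial mask empty: with >= 2 particles this means the
        # evaluator rejected the whole swarm
        raise RuntimeError("no valid (non-empty) mask in the initial swarm")

    history = [gbest_fit]
    stale = 0
    for _ in range(cfg.max_iter):
        improved = False
        for p in particles:
            p.velocity = update_velocity(p, gbest, cfg, rng)
            p.position = update_position(p, rng)
            fit = cached_fitness(p.position)
            if fit > p.pbest_fitness:
                p.pbest = p.position.copy()
                p.pbest_fitness = fit
                if fit > gbest_fit:
                    gbest = p.position.copy()
                    gbest_fit = fit
                    improved = True
        history.append(gbest_fit)
        stale = 0 if improved else stale + 1
        if stale >= cfg.patience:
            break
    return SwarmResult(
        gbest=FeatureMask(bits=gbest),
        gbest_fitness=float(gbest_fit),
        history=np.asarray(history),
        n_evaluations=n_evals,
    )
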