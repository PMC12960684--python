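"""Weight-optimized soft-voting ensemble fusion.

Each base classifier contributes an S x C row-stochastic class-probability
matrix; the ensemble output is the convex combination P_final = sum_k w_k P_k
with the weight vector constrained to the probability simplex.  The weights
are found by running a box-constrained metaheuristic over [0,1]^M with every
candidate mapped onto the simplex by clip-then-normalize before evaluation.
Two objectives are provided — ensemble accuracy (the default fitness) and
mean categorical cross-entropy — plus the conventional fixed fusion rules
(mean, product, hard voting, per-cell max, best single model and
accuracy-proportional weighting) as baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import baselines, eaoo
from .eaoo import Bounds, OptimizerConfig

__all__ = [
    "PredictionMatrix",
    "EnsembleResult",
    "CONVENTIONAL_RULES",
    "OPTIMIZERS",
    "normalize_to_simplex",
    "weighted_aggregate",
    "fitness_accuracy",
    "fitness_cross_entropy",
    "optimize_weights",
    "fuse_conventional",
    "predict",
    "load_prediction_matrix",
    "save_prediction_matrix",
    "load_labels",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12
_ROW_SUM_TOL = 1e-6


@dataclass
class PredictionMatrix:
    """Row-stochastic S x C class-probability matrix for one model.

    Rows are renormalized on construction; a row whose sum deviates from 1 by
    more than 1e-6 (or is non-positive / non-finite) is rejected.
    """

    probs: np.ndarray
    model_id: str = "model"
    class_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 2:
            raise ValueError("probs must be an S x C matrix with C >= 2")
        if not np.all(np.isfinite(p)):
            raise ValueError("probs must be finite")
        if np.any(p < 0):
            bad = np.unique(np.nonzero(p < 0)[0])
            raise ValueError(f"negative probabilities in rows {bad.tolist()}")
        sums = p.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"rows not stochastic within {_ROW_SUM_TOL}: {bad.tolist()}"
            )
        self.probs = p / sums[:, None]

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class EnsembleResult:
    """Outcome of an ensemble fusion: final probabilities, decisions, weights."""

    probs: np.ndarray  # S x C final ensemble probabilities
    labels: np.ndarray  # length-S argmax decisions
    objective_value: float
    weights: np.ndarray
    objective_name: str
    history: Optional[np.ndarray] = None


def _as_prob_stack(matrices: Sequence[PredictionMatrix]) -> np.ndarray:
    shapes = {m.probs.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"prediction matrices disagree in shape: {shapes}")
    return np.stack([m.probs for m in matrices])  # M x S x C


def normalize_to_simplex(raw: np.ndarray) -> np.ndarray:
    """Map a raw real vector onto the probability simplex.

    Negative entries are clipped to zero, then the vector is divided by its
    sum; the all-zero vector maps to the uniform point.
    """
    w = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total == 0.0:
        return np.full(w.size, 1.0 / w.size)
    return w / total


def weighted_aggregate(
    matrices: Sequence[PredictionMatrix], weights: np.ndarray
) -> np.ndarray:
    """Convex combination P_final = sum_k w_k P_k (rows stay stochastic)."""
    stack = _as_prob_stack(matrices)
    w = np.asarray(weights, dtype=float)
    if w.size != stack.shape[0]:
        raise ValueError("one weight per model is required")
    return np.tensordot(w, stack, axes=1)


def predict(p_final: np.ndarray) -> np.ndarray:
    """Row argmax; ties resolve to the lowest class index."""
    return np.argmax(np.asarray(p_final), axis=1)


def fitness_accuracy(
    weights: np.ndarray,
    matrices: Sequence[PredictionMatrix],
    labels: np.ndarray,
) -> float:
    """Fraction of samples whose weighted-ensemble argmax matches the label."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("label vector is empty")
    agg = weighted_aggregate(matrices, weights)
    return float(np.mean(predict(agg) == labels))


def fitness_cross_entropy(
    weights: np.ndarray,
    matrices: Sequence[PredictionMatrix],
    labels: np.ndarray,
) -> float:
    """Mean categorical cross-entropy of the weighted ensemble.

    Probabilities are floored at 1e-12 before the log.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("label vector is empty")
    agg = weighted_aggregate(matrices, weights)
    picked = np.clip(agg[np.arange(labels.size), labels], _PROB_FLOOR, None)
    return float(-np.mean(np.log(picked)))


# objective registry: name -> (fn, higher_is_better)
_OBJECTIVES: dict[str, tuple[Callable, bool]] = {
    "accuracy": (fitness_accuracy, True),
    "cross_entropy": (fitness_cross_entropy, False),
}

OPTIMIZERS = ("eaoo_ga", "aoo", "de", "ga", "random")


def _run_optimizer(
    name: str,
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: Optional[OptimizerConfig],
    rng: np.random.Generator,
    initial_points: Optional[np.ndarray],
) -> eaoo.OptimizationResult:
    if name in ("eaoo_ga", "aoo"):
        cfg = config or OptimizerConfig()
        if name == "aoo" and cfg.use_ga_operators:
            cfg = _replace(cfg, use_ga_operators=False)
        return eaoo.optimize(objective, bounds, cfg, rng, initial_points)
    cfg = config or OptimizerConfig()
    bcfg = baselines.BaselineConfig(
        algorithm=name,
        pop_size=cfg.pop_size,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
    )
    runners = {
        "de": baselines.optimize_de,
        "ga": baselines.optimize_ga,
        "random": baselines.optimize_random_search,
    }
    if name not in runners:
        raise ValueError(f"unknown optimizer {name!r}; choose from {OPTIMIZERS}")
    return runners[name](objective, bounds, bcfg, rng, initial_points)


def optimize_weights(
    matrices: Sequence[PredictionMatrix],
    labels: np.ndarray,
    objective: str = "accuracy",
    optimizer: str = "eaoo_ga",
    config: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> EnsembleResult:
    """Search the ensemble-weight simplex for the best fusion of the models.

    The optimizer runs over the box [0,1]^M; every candidate is mapped to the
    simplex (clip-then-normalize) before evaluation.  The initial population
    is warm-started with the uniform point and every one-hot vertex, so the
    result is never worse than the best single model or the plain average.
    """
    if len(matrices) < 2:
        raise ValueError("ensemble fusion needs at least 2 models")
    if objective not in _OBJECTIVES:
        raise ValueError(
            f"unknown objective {objective!r}; choose from {sorted(_OBJECTIVES)}"
        )
    labels = np.asarray(labels)
    fn, higher_is_better = _OBJECTIVES[objective]
    m = len(matrices)
    stack = _as_prob_stack(matrices)  # validated once; reused per candidate
    idx = np.arange(labels.size)

    def score(w_simplex: np.ndarray) -> float:
        agg = np.tensordot(w_simplex, stack, axes=1)
        if objective == "accuracy":
            return float(np.mean(np.argmax(agg, axis=1) == labels))
        picked = np.clip(agg[idx, labels], _PROB_FLOOR, None)
        return float(-np.mean(np.log(picked)))

    sign = -1.0 if higher_is_better else 1.0

    def box_objective(x: np.ndarray) -> float:
        return sign * score(normalize_to_simplex(x))

    bounds = Bounds.cube(0.0, 1.0, m)
    warm = np.vstack([np.full(m, 1.0 / m), np.eye(m)])
    if rng is None:
        rng = np.random.default_rng(config.seed if config else None)
    result = _run_optimizer(optimizer, box_objective, bounds, config, rng, warm)

    weights = normalize_to_simplex(result.best_position)
    final = weighted_aggregate(matrices, weights)
    value = fn(weights, matrices, labels)
    logger.info(
        "optimize_weights: optimizer=%s objective=%s value=%.6f weights=%s",
        optimizer, objective, value, np.round(weights, 4).tolist(),
    )
    return EnsembleResult(
        probs=final,
        labels=predict(final),
        objective_value=value,
        weights=weights,
        objective_name=objective,
        history=sign * result.history if higher_is_better else result.history,
    )


CONVENTIONAL_RULES = (
    "mean",
    "product",
    "hard_vote",
    "max_rule",
    "best_single",
    "fixed_weighted",
)


def _per_model_accuracy(
    matrices: Sequence[PredictionMatrix], labels: np.ndarray
) -> np.ndarray:
    return np.array(
        [np.mean(predict(m.probs) == labels) for m in matrices], dtype=float
    )


def fuse_conventional(
    matrices: Sequence[PredictionMatrix],
    labels: np.ndarray,
    rule: str,
) -> EnsembleResult:
    """Fixed (non-optimized) fusion rules used as comparison baselines.

    mean — unweighted average; product — elementwise product renormalized per
    row; hard_vote — majority of per-model argmax decisions (ties to the
    lowest class index); max_rule — per-cell maximum renormalized per row;
    best_single — the model with the highest individual accuracy;
    fixed_weighted — weights proportional to individual accuracies.
    """
    labels = np.asarray(labels)
    stack = _as_prob_stack(matrices)
    m, s, c = stack.shape
    weights = np.full(m, np.nan)
    if rule == "mean":
        final = stack.mean(axis=0)
        weights = np.full(m, 1.0 / m)
    elif rule == "product":
        final = stack.prod(axis=0)
        total = final.sum(axis=1, keepdims=True)
        # a row of all-zero products falls back to uniform
        final = np.where(total > 0, final / np.where(total > 0, total, 1.0), 1.0 / c)
    elif rule == "hard_vote":
        votes = np.argmax(stack, axis=2)  # M x S
        counts = np.zeros((s, c))
        for model_votes in votes:
            counts[np.arange(s), model_votes] += 1
        final = counts / m
    elif rule == "max_rule":
        final = stack.max(axis=0)
        final = final / final.sum(axis=1, keepdims=True)
    elif rule == "best_single":
        acc = _per_model_accuracy(matrices, labels)
        k = int(np.argmax(acc))
        final = stack[k]
        weights = np.eye(m)[k]
    elif rule == "fixed_weighted":
        acc = _per_model_accuracy(matrices, labels)
        weights = normalize_to_simplex(acc)
        final = np.tensordot(weights, stack, axes=1)
    else:
        raise ValueError(
            f"unknown fusion rule {rule!r}; choose from {CONVENTIONAL_RULES}"
        )
    decisions = predict(final)
    value = float(np.mean(decisions == labels))
    return EnsembleResult(
        probs=final,
        labels=decisions,
        objective_value=value,
        weights=weights,
        objective_name="accuracy",
    )


# ---------------------------------------------------------------------------
# File I/O: CSV with a header of class names, or .npy arrays


def load_prediction_matrix(
    path: Union[str, Path], model_id: Optional[str] = None
) -> PredictionMatrix:
    path = Path(path)
    model_id = model_id or path.stem
    if path.suffix == ".npy":
        probs = np.load(path)
        names = None
    else:
        frame = pd.read_csv(path)
        probs = frame.to_numpy(dtype=float)
        names = list(frame.columns)
    logger.info("loaded prediction matrix %s from %s", model_id, path)
    return PredictionMatrix(probs=probs, model_id=model_id, class_names=names)


def save_prediction_matrix(
    matrix: PredictionMatrix, path: Union[str, Path]
) -> None:
    path = Path(path)
    names = matrix.class_names or [
        f"class_{j}" for j in range(matrix.n_classes)
    ]
    pd.DataFrame(matrix.probs, columns=names).to_csv(path, index=False)
    logger.info("wrote prediction matrix %s to %s", matrix.model_id, path)


def load_labels(path: Union[str, Path]) -> np.ndarray:
    """Single-column CSV of integer class labels."""
    frame = pd.read_csv(path)
    if frame.shape[1] != 1:
        raise ValueError("label file must have exactly one column")
    labels = frame.iloc[:, 0].to_numpy(dtype=int)
    logger.info("loaded %d labels from %s", labels.size, path)
    return labels
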