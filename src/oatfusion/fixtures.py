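"""Synthetic inputs for every other module.

Generates classifier prediction matrices with planted weight structure,
benchmark objective functions with known minima, feature-map tensors with
analytic gradients for a linear scorer, and imbalanced Gaussian feature
clouds for the SMOTE pipeline.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .fusion import PredictionMatrix
from .preprocess import FeatureTable

__all__ = [
    "EnsembleScenario",
    "generate_prediction_matrices",
    "benchmark_objective",
    "BENCHMARKS",
    "generate_feature_maps",
    "generate_imbalanced_clusters",
]


@dataclass(frozen=True)
class EnsembleScenario:
    """Recipe for a synthetic multi-model classification scenario.

    ``accuracies`` sets each model's target probability of ranking the true
    class first.  ``correlation`` in [0, 1] makes models share per-sample
    "difficulty" draws, correlating their errors.  ``sharpness`` in (0.5, 1)
    is the probability mass placed deterministically on the intended argmax
    class (the remainder is a symmetric Dirichlet spread), emulating
    softmax-like confident rows while guaranteeing the intended argmax.
    """

    n_samples: int = 300
    n_classes: int = 3
    accuracies: Tuple[float, ...] = (0.9, 0.8, 0.7)
    correlation: float = 0.0
    sharpness: float = 0.7
    seed: Optional[int] = None

    @property
    def n_models(self) -> int:
        return len(self.accuracies)

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_classes < 2 or self.n_models < 1:
            raise ValueError("scenario sizes must be positive (C >= 2)")
        chance = 1.0 / self.n_classes
        for a in self.accuracies:
            if not chance <= a <= 1.0:
                raise ValueError(
                    f"accuracy target {a} outside [1/C, 1] = [{chance:.3f}, 1]"
                )
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [0, 1]")
        if not 0.5 < self.sharpness < 1.0:
            raise ValueError("sharpness must lie in (0.5, 1)")


def generate_prediction_matrices(
    scenario: EnsembleScenario,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[PredictionMatrix], np.ndarray]:
    """Draw per-model row-stochastic prediction matrices and true labels.

    Labels are uniform over classes.  For each model and sample, the row's
    mass concentrates on the true class with probability equal to the
    model's accuracy target, otherwise on a random wrong class; correlated
    models reuse a shared per-sample uniform draw for that decision.  Rows
    are sharpness * one_hot(target) + (1 - sharpness) * Dirichlet(1), so the
    intended argmax always wins (sharpness > 0.5).
    """
    scenario.validate()
    rng = rng or np.random.default_rng(scenario.seed)
    s, c = scenario.n_samples, scenario.n_classes
    labels = rng.integers(0, c, size=s)
    shared = rng.random(s)
    matrices: List[PredictionMatrix] = []
    for k, acc in enumerate(scenario.accuracies):
        own = rng.random(s)
        use_shared = rng.random(s) < scenario.correlation
        u = np.where(use_shared, shared, own)
        correct = u < acc
        wrong_offset = rng.integers(1, c, size=s)
        targets = np.where(correct, labels, (labels + wrong_offset) % c)
        spread = rng.dirichlet(np.ones(c), size=s)
        probs = (1.0 - scenario.sharpness) * spread
        probs[np.arange(s), targets] += scenario.sharpness
        matrices.append(
            PredictionMatrix(probs=probs, model_id=f"model_{k + 1}")
        )
    return matrices, labels


# ---------------------------------------------------------------------------
# Benchmark objectives


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    return float(
        np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
    )


def _ackley(x: np.ndarray) -> float:
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


#: name -> (objective, location of the global minimum as fn(dim), minimum value)
BENCHMARKS = {
    "sphere": (_sphere, lambda dim: np.zeros(dim), 0.0),
    "rastrigin": (_rastrigin, lambda dim: np.zeros(dim), 0.0),
    "rosenbrock": (_rosenbrock, lambda dim: np.ones(dim), 0.0),
    "ackley": (_ackley, lambda dim: np.zeros(dim), 0.0),
}


def benchmark_objective(
    name: str,
) -> Tuple[Callable[[np.ndarray], float], Callable[[int], np.ndarray], float]:
    """Return (objective, optimum-position factory, optimum value) by name."""
    if name not in BENCHMARKS:
        raise ValueError(
            f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}"
        )
    return BENCHMARKS[name]


# ---------------------------------------------------------------------------
# Feature maps with analytic gradients


def generate_feature_maps(
    h: int,
    w: int,
    c: int,
    structure: str = "random",
    rng: Optional[np.random.Generator] = None,
    scorer_coeffs: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reproducible H x W x C tensor plus analytic gradients of a linear scorer.

    The companion scorer is y = sum_m a_m * mean(F^m), whose gradient with
    respect to every spatial location of channel m is the constant a_m/(H*W);
    the returned gradient tensor is exactly that, so Grad-CAM channel weights
    computed from it equal a_m/(H*W) in closed form.

    ``structure`` — "random": nonnegative noise everywhere; "hot_channel":
    channel 0 carries a constant signal of 1 on top of the noise floor.
    """
    if min(h, w, c) < 1:
        raise ValueError("H, W, C must all be >= 1")
    rng = rng or np.random.default_rng()
    u = rng.random((h, w, c))
    if structure == "hot_channel":
        u[:, :, 0] += 1.0
    elif structure != "random":
        raise ValueError("structure must be 'random' or 'hot_channel'")
    if scorer_coeffs is None:
        scorer_coeffs = rng.normal(size=c)
    a = np.asarray(scorer_coeffs, dtype=float)
    if a.shape != (c,):
        raise ValueError("scorer_coeffs must have one entry per channel")
    grads = np.broadcast_to(a / (h * w), (h, w, c)).copy()
    return u, grads, a


def generate_imbalanced_clusters(
    counts: Sequence[int],
    dim: int = 2,
    separation: float = 5.0,
    scale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> FeatureTable:
    """Gaussian blobs with the requested per-class counts.

    Class c's mean sits at c * separation along the first axis, so
    consecutive class means are ``separation`` apart; each blob is isotropic
    with standard deviation ``scale``.
    """
    if len(counts) < 1 or any(n < 1 for n in counts):
        raise ValueError("each class needs a positive count")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = rng or np.random.default_rng()
    features = []
    labels = []
    for cls, n in enumerate(counts):
        mean = np.zeros(dim)
        mean[0] = cls * separation
        features.append(rng.normal(loc=mean, scale=scale, size=(n, dim)))
        labels.append(np.full(n, cls, dtype=int))
    return FeatureTable(
        features=np.vstack(features), labels=np.concatenate(labels)
    )
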