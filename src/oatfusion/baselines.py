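"""Reference optimizers for the comparison harness.

Differential Evolution (rand/1/bin), a real-coded genetic algorithm with
tournament selection, and uniform random search — all sharing the
:class:`~oatfusion.eaoo.OptimizationResult` contract so they can be swapped
into the ensemble-weight search and compared head to head.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .eaoo import Bounds, OptimizationResult, OptimizerConfig, _wrap_objective

__all__ = [
    "BaselineConfig",
    "optimize_de",
    "optimize_ga",
    "optimize_random_search",
]


@dataclass(frozen=True)
class BaselineConfig:
    """Settings for the reference optimizers.

    Defaults follow the shared comparison protocol: population 50 and 100
    iterations for every algorithm; DE uses rand/1/bin with F=0.5 and CR=0.7,
    the GA uses arithmetic crossover at probability 0.8, per-gene uniform
    reset mutation at 0.1 and tournament selection of size 3 with one elite.
    """

    algorithm: str = "de"
    pop_size: int = 50
    max_iter: int = 100
    de_scale_factor: float = 0.5
    de_crossover_rate: float = 0.7
    ga_crossover_prob: float = 0.8
    ga_mutation_prob: float = 0.1
    ga_tournament_size: int = 3
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.de_scale_factor > 0:
            raise ValueError("de_scale_factor must be > 0")
        if not 0.0 <= self.de_crossover_rate <= 1.0:
            raise ValueError("de_crossover_rate must lie in [0, 1]")
        if not 0.0 <= self.ga_crossover_prob <= 1.0:
            raise ValueError("ga_crossover_prob must lie in [0, 1]")
        if not 0.0 <= self.ga_mutation_prob <= 1.0:
            raise ValueError("ga_mutation_prob must lie in [0, 1]")
        if self.ga_tournament_size < 1:
            raise ValueError("ga_tournament_size must be >= 1")

    def as_optimizer_config(self) -> OptimizerConfig:
        # echoed inside OptimizationResult for uniform reporting
        return OptimizerConfig(
            pop_size=self.pop_size,
            max_iter=self.max_iter,
            scale_factor=self.de_scale_factor,
            crossover_rate=self.de_crossover_rate,
            seed=self.seed,
        )


def _init(bounds, config, rng, f, initial_points):
    n, dim = config.pop_size, bounds.dim
    pos = rng.random((n, dim)) * (bounds.upper - bounds.lower) + bounds.lower
    if initial_points is not None:
        pts = np.atleast_2d(np.asarray(initial_points, dtype=float))
        if pts.shape[1] != dim:
            raise ValueError("initial points must match the search dimension")
        k = min(pts.shape[0], n)
        pos[:k] = bounds.clip(pts[:k])
    fit = np.array([f(x) for x in pos])
    return pos, fit


def optimize_de(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: Optional[BaselineConfig] = None,
    rng: Optional[np.random.Generator] = None,
    initial_points: Optional[np.ndarray] = None,
) -> OptimizationResult:
    """Standard DE/rand/1/bin with greedy one-to-one replacement."""
    config = config or BaselineConfig(algorithm="de")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _wrap_objective(objective)
    pos, fit = _init(bounds, config, rng, f, initial_points)
    n, dim = pos.shape
    evaluations = n
    history = np.empty(config.max_iter)
    for g in range(config.max_iter):
        for i in range(n):
            others = np.delete(np.arange(n), i)
            r1, r2, r3 = rng.choice(others, size=3, replace=False)
            v = pos[r1] + config.de_scale_factor * (pos[r2] - pos[r3])
            j_rand = int(rng.integers(dim))
            mask = rng.random(dim) <= config.de_crossover_rate
            mask[j_rand] = True
            trial = bounds.clip(np.where(mask, v, pos[i]))
            ft = f(trial)
            evaluations += 1
            if ft <= fit[i]:
                pos[i], fit[i] = trial, ft
        history[g] = fit.min()
    history = np.minimum.accumulate(history)
    best = int(np.argmin(fit))
    return OptimizationResult(
        best_position=pos[best].copy(),
        best_fitness=float(fit[best]),
        history=history,
        evaluations=evaluations,
        config=config.as_optimizer_config(),
    )


def optimize_ga(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: Optional[BaselineConfig] = None,
    rng: Optional[np.random.Generator] = None,
    initial_points: Optional[np.ndarray] = None,
) -> OptimizationResult:
    """Real-coded GA: tournament(3) parents, arithmetic blend crossover,
    per-gene uniform-reset mutation, single-elite replacement."""
    config = config or BaselineConfig(algorithm="ga")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _wrap_objective(objective)
    pos, fit = _init(bounds, config, rng, f, initial_points)
    n, dim = pos.shape
    evaluations = n
    best_x = pos[np.argmin(fit)].copy()
    best_f = float(fit.min())
    history = np.empty(config.max_iter)

    def tournament() -> int:
        contenders = rng.integers(0, n, size=config.ga_tournament_size)
        return int(contenders[np.argmin(fit[contenders])])

    for g in range(config.max_iter):
        children = np.empty_like(pos)
        children[0] = best_x  # elitism
        idx = 1
        while idx < n:
            p1, p2 = pos[tournament()], pos[tournament()]
            if rng.random() < config.ga_crossover_prob:
                a = rng.random(dim)
                c1 = a * p1 + (1.0 - a) * p2
                c2 = a * p2 + (1.0 - a) * p1
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if idx >= n:
                    break
                reset = rng.random(dim) < config.ga_mutation_prob
                fresh = (
                    rng.random(dim) * (bounds.upper - bounds.lower)
                    + bounds.lower
                )
                children[idx] = bounds.clip(np.where(reset, fresh, child))
                idx += 1
        pos = children
        fit = np.array([f(x) for x in pos])
        evaluations += n
        g_best = int(np.argmin(fit))
        if fit[g_best] <= best_f:
            best_f = float(fit[g_best])
            best_x = pos[g_best].copy()
        history[g] = best_f
    return OptimizationResult(
        best_position=best_x,
        best_fitness=best_f,
        history=history,
        evaluations=evaluations,
        config=config.as_optimizer_config(),
    )


def optimize_random_search(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: Optional[BaselineConfig] = None,
    rng: Optional[np.random.Generator] = None,
    initial_points: Optional[np.ndarray] = None,
) -> OptimizationResult:
    """Pure random search: pop_size * max_iter independent uniform draws."""
    config = config or BaselineConfig(algorithm="random")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _wrap_objective(objective)
    dim = bounds.dim
    best_x: Optional[np.ndarray] = None
    best_f = np.inf
    evaluations = 0
    if initial_points is not None:
        for x in np.atleast_2d(np.asarray(initial_points, dtype=float)):
            x = bounds.clip(x)
            fx = f(x)
            evaluations += 1
            if fx <= best_f:
                best_f, best_x = fx, x.copy()
    history = np.empty(config.max_iter)
    for g in range(config.max_iter):
        draws = (
            rng.random((config.pop_size, dim)) * (bounds.upper - bounds.lower)
            + bounds.lower
        )
        for x in draws:
            fx = f(x)
            evaluations += 1
            if fx <= best_f:
                best_f, best_x = fx, x.copy()
        history[g] = best_f
    assert best_x is not None
    return OptimizationResult(
        best_position=best_x,
        best_fitness=float(best_f),
        history=history,
        evaluations=evaluations,
        config=config.as_optimizer_config(),
    )
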