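"""Enhanced Animated Oat Optimization with genetic operators (EAOO-GA).

A population metaheuristic for bound-constrained minimization that imitates
oat-seed dispersal: wind-driven displacement (exploration) and two exploitation
modes — hygroscopic rolling and elastic jumping — both perturbed by Levy
flights around the incumbent best. The enhanced variant interleaves a
differential-crossover step and a non-uniform mutation step (each gated by
greedy replacement) after the dispersal moves; switching ``use_ga_operators``
off recovers the plain AOO algorithm.

All moves are clipped to the search box, every replacement is greedy
(a trial survives only if its objective is no worse), so the best-so-far
trajectory is monotone non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "OptimizerConfig",
    "Population",
    "DynamicParams",
    "OptimizationResult",
    "initialize_population",
    "compute_dynamic_params",
    "levy_sigma",
    "levy_step",
    "exploration_step",
    "rolling_update",
    "jumping_update",
    "de_crossover",
    "nonuniform_mutation",
    "greedy_select",
    "optimize",
]

# Seed mass appears in a denominator of the jumping move; it is floored here
# to keep the step finite when the random draw is arbitrarily small.
_MASS_FLOOR = 1e-12


@dataclass(frozen=True)
class Bounds:
    """Axis-aligned search box with per-coordinate lower/upper limits."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("bounds must be 1-D vectors of equal length >= 1")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo > hi):
            raise ValueError("every lower bound must be <= its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def cube(cls, lower: float, upper: float, dim: int) -> "Bounds":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    """All EAOO-GA knobs.

    Defaults follow the reference hyperparameter table: population 50,
    100 iterations, differential scale factor F=0.5, crossover rate CR=0.9,
    mutation probability Pm=0.1, Levy stability exponent beta=1.5.

    ``p_explore`` / ``p_roll`` schedule the per-individual choice between
    exploration and exploitation and, within exploitation, between rolling
    and jumping (both Bernoulli, equiprobable by default).  ``mantegna_levy``
    switches the Levy scale from the as-printed form (pi in the denominator,
    uniform step numerator) to the standard Mantegna recipe.
    """

    pop_size: int = 50
    max_iter: int = 100
    scale_factor: float = 0.5
    crossover_rate: float = 0.9
    mutation_prob: float = 0.1
    nonuniformity: float = 5.0
    levy_beta: float = 1.5
    gravity: float = 9.81
    p_explore: float = 0.5
    p_roll: float = 0.5
    use_ga_operators: bool = True
    mantegna_levy: bool = False
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.pop_size < 4:
            raise ValueError(
                "pop_size must be >= 4 (differential crossover needs 3 "
                "distinct partners)"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be > 0")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if not self.nonuniformity > 0:
            raise ValueError("nonuniformity must be > 0")
        if not 0.0 < self.levy_beta <= 2.0:
            raise ValueError("levy_beta must lie in (0, 2]")
        if not self.gravity > 0:
            raise ValueError("gravity must be > 0")
        for name in ("p_explore", "p_roll"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Population:
    """Positions with fitness and the running best."""

    positions: np.ndarray  # N x Dim
    fitness: np.ndarray  # length N
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def note_candidate(self, x: np.ndarray, f: float) -> None:
        # strict improvement: on plateaus the earliest best is retained
        if f < self.best_fitness:
            self.best_fitness = float(f)
            self.best_position = np.array(x, dtype=float, copy=True)


@dataclass(frozen=True)
class DynamicParams:
    """Per-iteration biomechanical parameters of the dispersal model.

    ``m`` (seed mass) and ``e`` (eccentric rotation coefficient) are drawn
    uniformly from [0, 0.5/Dim], ``L`` (primary awn length) from [0, N/Dim];
    ``c`` = 1 - (t/T)^3 is the deterministic decay that shifts the search
    from exploration toward refinement.
    """

    m: float
    L: float
    e: float
    c: float


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness at the end of each iteration
    evaluations: int
    config: OptimizerConfig


def _wrap_objective(objective: Callable[[np.ndarray], float]):
    def safe(x: np.ndarray) -> float:
        v = float(objective(x))
        return v if math.isfinite(v) else math.inf

    return safe


def initialize_population(
    bounds: Bounds,
    config: OptimizerConfig,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    seeds: Optional[np.ndarray] = None,
) -> Population:
    """Draw the initial population uniformly in the box and evaluate it.

    Each entry is ``r * (UB_j - LB_j) + LB_j`` with independent r ~ U(0,1).
    ``seeds`` optionally overwrites the first rows with caller-supplied
    starting points (clipped to the box) — used to warm-start the ensemble
    weight search.
    """
    config.validate()
    n, dim = config.pop_size, bounds.dim
    r = rng.random((n, dim))
    positions = r * (bounds.upper - bounds.lower) + bounds.lower
    if seeds is not None:
        seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
        if seeds.shape[1] != dim:
            raise ValueError("seed points must match the search dimension")
        k = min(seeds.shape[0], n)
        positions[:k] = bounds.clip(seeds[:k])
    f = _wrap_objective(objective)
    fitness = np.array([f(x) for x in positions])
    best = int(np.argmin(fitness))
    return Population(
        positions=positions,
        fitness=fitness,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
        iteration=0,
    )


def compute_dynamic_params(
    t: int, T: int, N: int, dim: int, rng: np.random.Generator
) -> DynamicParams:
    """Sample the per-iteration dispersal parameters.

    m = 0.5 r / Dim,  L = N r / Dim,  e = 0.5 r / Dim  (fresh r each) and the
    deterministic decay c = 1 - (t/T)^3.
    """
    if T < 1:
        raise ValueError("total iterations T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError("iteration t must lie in [0, T]")
    m = 0.5 * rng.random() / dim
    L = N * rng.random() / dim
    e = 0.5 * rng.random() / dim
    c = 1.0 - (t / T) ** 3
    return DynamicParams(m=m, L=L, e=e, c=c)


def levy_sigma(beta: float, mantegna: bool = False) -> float:
    """Scale parameter of the Levy step-length distribution.

    The default reproduces the as-printed formula

        sigma = [ Gamma(1+beta) sin(pi beta / 2)
                  / ( Gamma((1+beta)/2) * pi * 2^((beta-1)/2) ) ]^(1/beta)

    with the undefined exponent rho read as beta.  ``mantegna=True`` replaces
    the pi in the denominator with beta, giving the standard Mantegna scale.
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    mid = beta if mantegna else math.pi
    den = math.gamma((1.0 + beta) / 2.0) * mid * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(
    dim: int,
    beta: float,
    rng: np.random.Generator,
    mantegna: bool = False,
) -> np.ndarray:
    """Heavy-tailed random step, elementwise ``0.01 * mu * sigma / |nu|^(1/beta)``.

    In the default (as-printed) mode mu ~ U(0,1) per component and nu is
    standard normal.  In Mantegna mode the numerator is a single normal draw
    with standard deviation sigma (the conventional recipe).
    """
    sigma = levy_sigma(beta, mantegna=mantegna)
    if mantegna:
        num = rng.normal(0.0, sigma, size=dim)
    else:
        num = rng.random(dim) * sigma
    nu = rng.standard_normal(dim)
    return 0.01 * num / np.abs(nu) ** (1.0 / beta)


def _exploration_candidate(
    index: int,
    pop: Population,
    bounds: Bounds,
    params: DynamicParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Wind-dispersal move for one individual (1-based branch index).

    W = (c/pi) (2 r_Dim - 1) ⊗ UB; the branch cycles with period
    s = max(1, floor(N/10)): population-mean anchor when mod(i, s) = 0,
    best anchor when mod(i, s) = 1, otherwise the individual itself.
    """
    n, dim = pop.size, pop.dim
    w = (params.c / math.pi) * (2.0 * rng.random(dim) - 1.0) * bounds.upper
    s = max(1, n // 10)
    branch = (index + 1) % s  # 1-based individual index
    if branch == 0:
        anchor = pop.positions.mean(axis=0)
    elif branch == 1:
        anchor = pop.best_position
    else:
        anchor = pop.positions[index]
    return bounds.clip(anchor + w)


def exploration_step(
    pop: Population,
    bounds: Bounds,
    params: DynamicParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the wind-dispersal move to every individual; returns new positions."""
    return np.stack(
        [
            _exploration_candidate(i, pop, bounds, params, rng)
            for i in range(pop.size)
        ]
    )


def rolling_update(
    index: int,
    pop: Population,
    bounds: Bounds,
    params: DynamicParams,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hygroscopic-rolling exploitation move.

    A = UB - |UB t sin(2 pi r) / T| (elementwise, scalar r fresh);
    R = (m e + L^2) * U(-A, A) / Dim; the candidate is
    X_best + R + c * Levy ⊗ X_best, clipped to the box.
    """
    t, T = pop.iteration, config.max_iter
    r = rng.random()
    a = bounds.upper - np.abs(bounds.upper * t * math.sin(2.0 * math.pi * r) / T)
    roll = (params.m * params.e + params.L**2) * rng.uniform(-a, a) / pop.dim
    levy = levy_step(pop.dim, config.levy_beta, rng, mantegna=config.mantegna_levy)
    return bounds.clip(pop.best_position + roll + params.c * levy * pop.best_position)


def jumping_update(
    index: int,
    pop: Population,
    bounds: Bounds,
    params: DynamicParams,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Elastic-jumping exploitation move.

    B = UB - |UB t cos(2 pi r) / T|; with one scalar r shared by the awn
    elasticity k = 0.5 + 0.5 r, the length change x = 3 r / Dim and the launch
    angle theta = pi r, and drag alpha = exp(r'/T)/pi with r' ~ U(0, T), the
    jump is J = 2 k x^2 sin(2 theta) / (m g) * U(-B, B)/Dim * (1 - alpha).
    """
    t, T = pop.iteration, config.max_iter
    r = rng.random()
    b = bounds.upper - np.abs(bounds.upper * t * math.cos(2.0 * math.pi * r) / T)
    k = 0.5 + 0.5 * r
    x = 3.0 * r / pop.dim
    theta = math.pi * r
    r_prime = rng.uniform(0.0, T)
    alpha = math.exp(r_prime / T) / math.pi
    m = max(params.m, _MASS_FLOOR)
    jump = (
        (2.0 * k * x**2 * math.sin(2.0 * theta))
        / (m * config.gravity)
        * (rng.uniform(-b, b) / pop.dim)
        * (1.0 - alpha)
    )
    levy = levy_step(pop.dim, config.levy_beta, rng, mantegna=config.mantegna_levy)
    return bounds.clip(pop.best_position + jump + params.c * levy * pop.best_position)


def de_crossover(
    pop: Population,
    target_index: int,
    bounds: Bounds,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Differential trial vector: V = X_r1 + F (X_r2 - X_r3), binomial crossover.

    r1, r2, r3 are distinct and differ from the target; one coordinate
    (j_rand) always inherits from V.
    """
    n, dim = pop.size, pop.dim
    if n < 4:
        raise ValueError("differential crossover needs a population of >= 4")
    others = np.delete(np.arange(n), target_index)
    r1, r2, r3 = rng.choice(others, size=3, replace=False)
    v = pop.positions[r1] + config.scale_factor * (
        pop.positions[r2] - pop.positions[r3]
    )
    j_rand = int(rng.integers(dim))
    mask = rng.random(dim) <= config.crossover_rate
    mask[j_rand] = True
    return bounds.clip(np.where(mask, v, pop.positions[target_index]))


def nonuniform_mutation(
    position: np.ndarray,
    bounds: Bounds,
    t: int,
    T: int,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutation whose reach Delta(t, y) = y (1 - r^((1 - t/T)^b)) decays to 0.

    Each coordinate mutates independently with probability Pm; a coin flip
    chooses the direction (toward UB or LB), so the mutant stays in the box
    by construction.
    """
    x = np.array(position, dtype=float, copy=True)
    dim = x.size
    mutate = rng.random(dim) < config.mutation_prob
    up = rng.random(dim) < 0.5
    r = rng.random(dim)
    exponent = (1.0 - t / T) ** config.nonuniformity
    shrink = 1.0 - r**exponent
    y_up = bounds.upper - x
    y_down = x - bounds.lower
    delta = np.where(up, y_up, y_down) * shrink
    x = np.where(mutate, np.where(up, x + delta, x - delta), x)
    return bounds.clip(x)


def greedy_select(current_fitness: float, trial_fitness: float) -> bool:
    """Keep the trial iff its objective is no worse (minimization, inclusive)."""
    if not math.isfinite(trial_fitness):
        return False
    return trial_fitness <= current_fitness


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: Optional[OptimizerConfig] = None,
    rng: Optional[np.random.Generator] = None,
    initial_points: Optional[np.ndarray] = None,
) -> OptimizationResult:
    """Run EAOO-GA (or plain AOO when ``use_ga_operators`` is off).

    Per iteration: fresh dispersal parameters; each individual explores with
    probability ``p_explore`` or exploits (rolling vs jumping with probability
    ``p_roll``), every move accepted greedily; then, in the enhanced variant,
    a population-wide differential-crossover pass and a non-uniform-mutation
    pass, each greedy-gated.  Non-finite objective values are treated as +inf.
    """
    config = config or OptimizerConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _wrap_objective(objective)
    pop = initialize_population(bounds, config, rng, f, seeds=initial_points)
    evaluations = pop.size
    T = config.max_iter
    history = np.empty(T)

    for t in range(1, T + 1):
        pop.iteration = t
        params = compute_dynamic_params(t, T, pop.size, pop.dim, rng)

        for i in range(pop.size):
            if rng.random() < config.p_explore:
                cand = _exploration_candidate(i, pop, bounds, params, rng)
            elif rng.random() < config.p_roll:
                cand = rolling_update(i, pop, bounds, params, config, rng)
            else:
                cand = jumping_update(i, pop, bounds, params, config, rng)
            fc = f(cand)
            evaluations += 1
            if greedy_select(pop.fitness[i], fc):
                pop.positions[i] = cand
                pop.fitness[i] = fc
                pop.note_candidate(cand, fc)

        if config.use_ga_operators:
            for i in range(pop.size):
                trial = de_crossover(pop, i, bounds, config, rng)
                ft = f(trial)
                evaluations += 1
                if greedy_select(pop.fitness[i], ft):
                    pop.positions[i] = trial
                    pop.fitness[i] = ft
                    pop.note_candidate(trial, ft)
            for i in range(pop.size):
                mutant = nonuniform_mutation(
                    pop.positions[i], bounds, t, T, config, rng
                )
                fm = f(mutant)
                evaluations += 1
                if greedy_select(pop.fitness[i], fm):
                    pop.positions[i] = mutant
                    pop.fitness[i] = fm
                    pop.note_candidate(mutant, fm)

        history[t - 1] = pop.best_fitness

    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        history=history,
        evaluations=evaluations,
        config=config,
    )
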