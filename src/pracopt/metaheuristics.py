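"""Real-coded GA, continuous ACO, and the hybrid network trainers.

Both metaheuristics minimize a black-box objective over a box.  For the
hybrid trainers the objective is the scaled-space training MSE of the
4-h-1 surrogate as a function of its flattened weight/threshold vector,
searched within [-3, 3] per parameter (tanh saturates beyond that once
inputs are scaled to [-1, 1]).

GA: tournament selection (size 2), arithmetic blend crossover, per-gene
Gaussian mutation with sigma = 10 % of the gene's bound width, one-elite
elitism.  Elitism makes the per-generation best monotone, which is part of
the contract.

ACO (continuous domain, discretized): each parameter gets a fixed candidate
grid and a pheromone value per candidate.  An ant picks, per parameter, the
highest-pheromone candidate with probability ``q0`` (the "transition
probability constant") and otherwise samples proportionally to pheromone.
After each iteration the pheromone decays by the retention factor (the
"volatilization coefficient" 0.9 is read as tau <- 0.9*tau + deposit; the
alternative reading, evaporation 0.9 hence retention 0.1, is a config away)
and the iteration-best path receives a deposit normalized so that the
initial total pheromone equals ``total_pheromone``.

The GA-ACO hybrid follows a three-stage schedule: a GA over per-candidate
pheromone-bias vectors scored by short ACO probes picks the initial
pheromone field, a full ACO run with that field searches the weight space,
and backpropagation refines the best ant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .surrogate_nn import (
    DataScaler,
    NetworkParams,
    TrainConfig,
    scaled_mse,
    train_bp,
)

__all__ = [
    "GAConfig",
    "ACOConfig",
    "FitnessTrace",
    "HybridReport",
    "ga_minimize",
    "aco_minimize",
    "train_ga_bp",
    "train_ga_aco_bp",
]

_PENALTY = 1e12
#: Default per-parameter search interval for network weights in scaled space.
WEIGHT_BOUNDS = (-3.0, 3.0)


@dataclass(frozen=True)
class GAConfig:
    """Published GA hyperparameters: population 30, 50 generations,
    crossover probability 0.8, mutation probability 0.2."""

    pop_size: int = 30
    generations: int = 50
    p_crossover: float = 0.8
    p_mutation: float = 0.2
    bounds: tuple[float, float] = WEIGHT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ACOConfig:
    """Published ACO hyperparameters: retention (volatilization coefficient)
    0.9, greedy-selection probability q0 = 0.2, total pheromone 1."""

    n_ants: int = 30
    iterations: int = 50
    retention: float = 0.9
    q0: float = 0.2
    total_pheromone: float = 1.0
    n_candidates_per_dim: int = 40
    bounds: tuple[float, float] = WEIGHT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.retention < 1.0:
            raise ValueError("retention must lie in (0, 1)")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must lie in [0, 1]")
        if self.n_candidates_per_dim < 2:
            raise ValueError("need at least 2 candidates per dimension")


@dataclass
class FitnessTrace:
    """Per-generation (or per-iteration) best-so-far and population mean."""

    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    last_improvement: int | None = None

    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate(np.asarray(self.best))


def _resolve_bounds(bounds, dim: int) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.shape == (2,):
        b = np.tile(b, (dim, 1))
    if b.shape != (dim, 2) or np.any(b[:, 0] >= b[:, 1]):
        raise ValueError("bounds must be (low, high) or per-gene pairs with low < high")
    return b


def _safe(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    v = float(objective(x))
    return v if np.isfinite(v) else _PENALTY


def ga_minimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    config: GAConfig | None = None,
) -> tuple[np.ndarray, float, FitnessTrace]:
    """Minimize ``objective`` over the box with a real-coded GA.

    Deterministic under ``config.seed``; non-finite objective values are
    penalized rather than fatal.
    """
    config = config or GAConfig()
    bounds = _resolve_bounds(config.bounds, dim)
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    rng = np.random.default_rng(config.seed)

    pop = rng.uniform(lo, hi, size=(config.pop_size, dim))
    fit = np.array([_safe(objective, ind) for ind in pop])
    trace = FitnessTrace()
    best_idx = int(np.argmin(fit))
    best_x, best_val = pop[best_idx].copy(), float(fit[best_idx])

    def tournament() -> np.ndarray:
        i, j = rng.integers(config.pop_size, size=2)
        return pop[i] if fit[i] <= fit[j] else pop[j]

    for _ in range(config.generations):
        children = [best_x.copy()]  # elitism
        while len(children) < config.pop_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.p_crossover:
                u = rng.random()
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mutate = rng.random(dim) < config.p_mutation
            if mutate.any():
                child = child + mutate * rng.normal(0.0, 0.1 * width, dim)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fit = np.array([_safe(objective, ind) for ind in pop])
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_val:
            best_val = float(fit[gen_best])
            best_x = pop[gen_best].copy()
        trace.best.append(best_val)
        trace.mean.append(float(fit.mean()))
    return best_x, best_val, trace


def _candidate_grid(config: ACOConfig, dim: int) -> np.ndarray:
    bounds = _resolve_bounds(config.bounds, dim)
    return np.linspace(bounds[:, 0], bounds[:, 1], config.n_candidates_per_dim).T


def aco_minimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    config: ACOConfig | None = None,
    initial_pheromone: np.ndarray | None = None,
) -> tuple[np.ndarray, float, FitnessTrace]:
    """Minimize ``objective`` with grid-discretized continuous ACO.

    ``initial_pheromone`` (dim, n_candidates) is normalized so its total
    equals ``total_pheromone``; by default the field starts uniform.
    """
    config = config or ACOConfig()
    grid = _candidate_grid(config, dim)  # (dim, m)
    m = config.n_candidates_per_dim
    rng = np.random.default_rng(config.seed)

    if initial_pheromone is not None:
        tau = np.asarray(initial_pheromone, dtype=float).copy()
        if tau.shape != (dim, m):
            raise ValueError(f"initial_pheromone must have shape ({dim}, {m})")
        if np.any(tau < 0) or tau.sum() <= 0:
            raise ValueError("initial_pheromone must be nonnegative with positive sum")
        tau *= config.total_pheromone / tau.sum()
    else:
        tau = np.full((dim, m), config.total_pheromone / (dim * m))
    deposit = (1.0 - config.retention) * config.total_pheromone / dim

    best_x: np.ndarray | None = None
    best_val = np.inf
    best_choice: np.ndarray | None = None
    trace = FitnessTrace(last_improvement=None)

    for it in range(config.iterations):
        greedy = tau.argmax(axis=1)  # ties -> lowest index
        row_sums = tau.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(row_sums > 0, tau / row_sums, 1.0 / m)
        cum = np.cumsum(probs, axis=1)
        it_best_val = np.inf
        it_best_choice = None
        it_vals = []
        for _ in range(config.n_ants):
            use_greedy = rng.random(dim) < config.q0
            draws = rng.random(dim)
            roulette = (cum < draws[:, None]).sum(axis=1).clip(max=m - 1)
            choice = np.where(use_greedy, greedy, roulette)
            x = grid[np.arange(dim), choice]
            v = _safe(objective, x)
            it_vals.append(v)
            if v < it_best_val:
                it_best_val = v
                it_best_choice = choice
        if it_best_val < best_val:
            best_val = float(it_best_val)
            best_choice = it_best_choice
            best_x = grid[np.arange(dim), it_best_choice].copy()
            trace.last_improvement = it
        tau *= config.retention
        tau[np.arange(dim), it_best_choice] += deposit
        trace.best.append(best_val)
        trace.mean.append(float(np.mean(it_vals)))
    assert best_x is not None
    return best_x, best_val, trace


@dataclass
class HybridReport:
    """Per-stage objective values and traces of a hybrid training run."""

    stage_mse: dict[str, float]
    ga_trace: FitnessTrace | None = None
    aco_trace: FitnessTrace | None = None
    bp_history: list[float] = field(default_factory=list)

    @property
    def aco_last_improvement(self) -> int | None:
        return None if self.aco_trace is None else self.aco_trace.last_improvement


def _mse_objective(
    X: np.ndarray, y: np.ndarray, n_in: int, h: int
) -> tuple[Callable[[np.ndarray], float], DataScaler]:
    scaler = DataScaler().fit(X, y)
    Xs = scaler.x.transform(X)
    ys = scaler.y.transform(np.asarray(y, dtype=float).reshape(-1, 1))[:, 0]

    def objective(vec: np.ndarray) -> float:
        return scaled_mse(NetworkParams.from_vector(vec, n_in, h), Xs, ys)

    return objective, scaler


def train_ga_bp(
    data: tuple[np.ndarray, np.ndarray],
    h: int,
    ga: GAConfig | None = None,
    bp: TrainConfig | None = None,
) -> tuple[NetworkParams, HybridReport]:
    """GA over the flattened weight vector, then backpropagation refinement.

    The GA minimizes the training MSE of the decoded network; its best
    individual initializes gradient descent.  Deterministic under
    (ga.seed, bp.seed); refinement cannot worsen the training MSE because
    backpropagation returns its best-seen parameters.
    """
    ga = ga or GAConfig()
    bp = bp or TrainConfig()
    X, y = (np.asarray(a, dtype=float) for a in data)
    n_in = X.shape[1]
    dim = NetworkParams.n_params(n_in, h)
    objective, scaler = _mse_objective(X, y, n_in, h)
    best_vec, ga_best, ga_trace = ga_minimize(objective, dim, ga)
    init = NetworkParams.from_vector(best_vec, n_in, h, scaler=scaler)
    params, history = train_bp(data, h, bp, init=init)
    report = HybridReport(
        stage_mse={"ga": ga_best, "bp": min(history)},
        ga_trace=ga_trace,
        bp_history=history,
    )
    return params, report


def _probe_initial_pheromone(
    bias: np.ndarray, dim: int, total: float
) -> np.ndarray:
    """Expand a per-candidate bias vector into a (dim, m) pheromone field."""
    bias = np.clip(np.asarray(bias, dtype=float), 1e-9, None)
    tau = np.tile(bias, (dim, 1))
    return tau * (total / tau.sum())


def train_ga_aco_bp(
    data: tuple[np.ndarray, np.ndarray],
    h: int,
    ga: GAConfig | None = None,
    aco: ACOConfig | None = None,
    bp: TrainConfig | None = None,
    probe_iterations: int = 5,
    probe_ants: int = 10,
) -> tuple[NetworkParams, HybridReport]:
    """Three-stage hybrid: GA-chosen pheromone field, ACO search, BP refinement.

    Stage 1: a GA searches per-candidate pheromone-bias vectors (one gene per
    column of the candidate grid, shared across parameters); each bias is
    scored by the best training MSE a short, fixed-seed ACO probe reaches
    when started from that field.  Stage 2: a full ACO run with the winning
    field minimizes the training MSE over the flattened weight vector.
    Stage 3: backpropagation refines the best ant.  The stage objectives are
    nonincreasing from stage 2 to stage 3 by construction.
    """
    ga = ga or GAConfig(bounds=(0.01, 1.0))
    aco = aco or ACOConfig()
    bp = bp or TrainConfig()
    X, y = (np.asarray(a, dtype=float) for a in data)
    n_in = X.shape[1]
    dim = NetworkParams.n_params(n_in, h)
    objective, scaler = _mse_objective(X, y, n_in, h)

    probe_cfg = replace(
        aco, iterations=probe_iterations, n_ants=probe_ants, seed=aco.seed
    )

    def probe_score(bias: np.ndarray) -> float:
        tau0 = _probe_initial_pheromone(bias, dim, aco.total_pheromone)
        _, val, _ = aco_minimize(objective, dim, probe_cfg, initial_pheromone=tau0)
        return val

    ga_cfg = replace(ga, bounds=(0.01, 1.0))
    best_bias, ga_best, ga_trace = ga_minimize(
        probe_score, aco.n_candidates_per_dim, ga_cfg
    )

    tau0 = _probe_initial_pheromone(best_bias, dim, aco.total_pheromone)
    best_vec, aco_best, aco_trace = aco_minimize(
        objective, dim, aco, initial_pheromone=tau0
    )

    init = NetworkParams.from_vector(best_vec, n_in, h, scaler=scaler)
    params, history = train_bp(data, h, bp, init=init)
    report = HybridReport(
        stage_mse={"ga": ga_best, "aco": aco_best, "bp": min(history)},
        ga_trace=ga_trace,
        aco_trace=aco_trace,
        bp_history=history,
    )
    return params, report
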