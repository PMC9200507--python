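"""Canonical comparison heuristics for the feature-selection harness.

Greedy forward stepwise (GSS), best-first subset search (BFS), a genetic
algorithm (GS), and binary particle swarm optimization (PSO). All four score
candidate subsets with the same memoized :class:`~mmaselect.search.FitnessEvaluator`
as the memory-buffer search, so comparisons across methods see an identical
fitness landscape. Parameters are fixed textbook defaults; these baselines
exist to make the comparison reproducible, not to replicate any particular
legacy toolkit.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .search import (
    FeatureSubset,
    FitnessEvaluator,
    SearchConfig,
    SelectionResult,
    neighborhood,
    subset_key,
)
from .tabular import DataTable


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "greedy_stepwise"
    # genetic algorithm
    population: int = 20
    generations: int = 50
    crossover_rate: float = 0.6
    mutation_rate: float | None = None  # None -> 1/d
    elitism: int = 1
    tournament: int = 2
    # binary PSO
    swarm: int = 20
    pso_iterations: int = 50
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    v_clamp: float = 6.0
    # best-first
    bfs_stall_limit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.crossover_rate,):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if min(self.population, self.generations, self.swarm, self.pso_iterations) < 1:
            raise ValueError("counts must be >= 1")


def _result(
    method: str,
    best: FeatureSubset,
    best_fit: float,
    trajectory: list[tuple[float, float]],
    iterations: int,
    evaluator: FitnessEvaluator,
) -> SelectionResult:
    return SelectionResult(
        method=method,
        best_subset=best,
        best_fitness=best_fit,
        trajectory=trajectory,
        iterations_run=iterations,
        n_evaluations=evaluator.n_evaluations,
        feature_names=list(evaluator.feature_names),
    )


def greedy_stepwise(
    table: DataTable,
    config: BaselineConfig = BaselineConfig(),
    search_config: SearchConfig = SearchConfig(),
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Forward selection: start from the best singleton, repeatedly add the
    feature with the largest strict fitness gain, stop when none improves."""
    evaluator = evaluator or FitnessEvaluator(table, search_config)
    d = table.n_cols
    singletons = [FeatureSubset.from_indices([i], d) for i in range(d)]
    current = min(singletons, key=lambda s: subset_key(evaluator(s), s))
    current_fit = evaluator(current)
    trajectory = [(current_fit, current_fit)]
    iterations = 1
    while True:
        additions = [
            current.flip(i) for i in range(d) if not current.mask[i]
        ]
        if not additions:
            break
        iterations += 1
        best_add = min(additions, key=lambda s: subset_key(evaluator(s), s))
        if evaluator(best_add) > current_fit:  # strict improvement only
            current, current_fit = best_add, evaluator(best_add)
            trajectory.append((current_fit, current_fit))
        else:
            break
    return _result("greedy_stepwise", current, current_fit, trajectory, iterations, evaluator)


def best_first(
    table: DataTable,
    config: BaselineConfig = BaselineConfig(),
    search_config: SearchConfig = SearchConfig(),
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Best-first subset search with backtracking.

    A priority queue orders unexpanded subsets by fitness (ties broken like
    everywhere else); each expansion opens the Hamming-1 neighborhood.
    Terminates after ``bfs_stall_limit`` consecutive expansions that fail to
    improve the best subset, or when the queue empties.
    """
    evaluator = evaluator or FitnessEvaluator(table, search_config)
    d = table.n_cols
    heap: list[tuple] = []
    visited: set[tuple[bool, ...]] = set()
    counter = 0  # FIFO tie-break stabilizer for identical keys
    for i in range(d):
        s = FeatureSubset.from_indices([i], d)
        heapq.heappush(heap, (subset_key(evaluator(s), s), counter, s))
        visited.add(s.mask)
        counter += 1
    best: FeatureSubset | None = None
    best_fit = -np.inf
    trajectory: list[tuple[float, float]] = []
    stall = 0
    expansions = 0
    while heap and stall < config.bfs_stall_limit:
        _, _, subset = heapq.heappop(heap)
        fit = evaluator(subset)
        expansions += 1
        if best is None or subset_key(fit, subset) < subset_key(best_fit, best):
            best, best_fit = subset, fit
            stall = 0
        else:
            stall += 1
        trajectory.append((fit, best_fit))
        for neighbor in neighborhood(subset):
            if neighbor.mask not in visited:
                visited.add(neighbor.mask)
                heapq.heappush(
                    heap, (subset_key(evaluator(neighbor), neighbor), counter, neighbor)
                )
                counter += 1
    assert best is not None
    return _result("best_first", best, best_fit, trajectory, expansions, evaluator)


def _repair_empty(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def genetic_select(
    table: DataTable,
    config: BaselineConfig = BaselineConfig(),
    search_config: SearchConfig = SearchConfig(),
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Canonical GA: tournament selection, uniform crossover, bit-flip
    mutation, one elite carried per generation; returns the best individual
    ever evaluated."""
    if config.population < 2:
        raise ValueError("population must be >= 2")
    evaluator = evaluator or FitnessEvaluator(table, search_config)
    d = table.n_cols
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / d

    def as_subset(mask: np.ndarray) -> FeatureSubset:
        return FeatureSubset(tuple(bool(b) for b in mask))

    pop = [
        _repair_empty(rng.integers(0, 2, size=d).astype(bool), rng)
        for _ in range(config.population)
    ]
    fits = [evaluator(as_subset(m)) for m in pop]
    order = min(range(len(pop)), key=lambda i: subset_key(fits[i], as_subset(pop[i])))
    best, best_fit = as_subset(pop[order]), fits[order]
    trajectory = [(best_fit, best_fit)]

    for _ in range(config.generations):
        new_pop = [np.array(best.mask)]  # elitism
        while len(new_pop) < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), size=config.tournament)
                winner = min(
                    contenders,
                    key=lambda i: subset_key(fits[i], as_subset(pop[i])),
                )
                parents.append(pop[winner])
            if rng.random() < config.crossover_rate:
                swap = rng.random(d) < 0.5
                child = np.where(swap, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(d) < mut_rate
            child = np.logical_xor(child, flip)
            new_pop.append(_repair_empty(child, rng))
        pop = new_pop
        fits = [evaluator(as_subset(m)) for m in pop]
        gen_best = min(
            range(len(pop)), key=lambda i: subset_key(fits[i], as_subset(pop[i]))
        )
        cand, cand_fit = as_subset(pop[gen_best]), fits[gen_best]
        if subset_key(cand_fit, cand) < subset_key(best_fit, best):
            best, best_fit = cand, cand_fit
        trajectory.append((cand_fit, best_fit))
    return _result("genetic", best, best_fit, trajectory, config.generations, evaluator)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def pso_select(
    table: DataTable,
    config: BaselineConfig = BaselineConfig(),
    search_config: SearchConfig = SearchConfig(),
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Binary PSO with a sigmoid transfer function and velocity clamping."""
    if config.swarm < 2:
        raise ValueError("swarm must be >= 2")
    evaluator = evaluator or FitnessEvaluator(table, search_config)
    d = table.n_cols
    rng = np.random.default_rng(config.seed)

    def as_subset(mask: np.ndarray) -> FeatureSubset:
        return FeatureSubset(tuple(bool(b) for b in mask))

    pos = np.stack(
        [
            _repair_empty(rng.integers(0, 2, size=d).astype(bool), rng)
            for _ in range(config.swarm)
        ]
    )
    vel = rng.uniform(-1, 1, size=(config.swarm, d))
    fits = np.array([evaluator(as_subset(p)) for p in pos])
    pbest = pos.copy()
    pbest_fit = fits.copy()
    g = min(
        range(config.swarm), key=lambda i: subset_key(fits[i], as_subset(pos[i]))
    )
    gbest, gbest_fit = as_subset(pos[g]), float(fits[g])
    trajectory = [(float(fits[g]), gbest_fit)]

    for _ in range(config.pso_iterations):
        r1 = rng.random((config.swarm, d))
        r2 = rng.random((config.swarm, d))
        gbest_arr = np.array(gbest.mask, dtype=float)
        vel = (
            config.inertia * vel
            + config.c1 * r1 * (pbest.astype(float) - pos.astype(float))
            + config.c2 * r2 * (gbest_arr - pos.astype(float))
        )
        np.clip(vel, -config.v_clamp, config.v_clamp, out=vel)
        pos = rng.random((config.swarm, d)) < _sigmoid(vel)
        pos = np.stack([_repair_empty(p, rng) for p in pos])
        fits = np.array([evaluator(as_subset(p)) for p in pos])
        iter_best = -np.inf
        for i in range(config.swarm):
            cand = as_subset(pos[i])
            if subset_key(fits[i], cand) < subset_key(
                pbest_fit[i], as_subset(pbest[i])
            ):
                pbest[i] = pos[i]
                pbest_fit[i] = fits[i]
            if subset_key(fits[i], cand) < subset_key(gbest_fit, gbest):
                gbest, gbest_fit = cand, float(fits[i])
            iter_best = max(iter_best, float(fits[i]))
        trajectory.append((iter_best, gbest_fit))
    return _result("pso", gbest, gbest_fit, trajectory, config.pso_iterations, evaluator)


BASELINES = {
    "greedy_stepwise": greedy_stepwise,
    "best_first": best_first,
    "genetic": genetic_select,
    "pso": pso_select,
}
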