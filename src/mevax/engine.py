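"""The generational loop: evaluate, rank + niche, select, cross, mutate.

Each generation builds a fresh stratified CV plan (seed = base seed +
generation number), evaluates every chromosome on it, ranks the population
into niched Pareto fronts, copies the first front (capped at half the
population) as elites, and fills the remainder with mutated uniform-crossover
offspring of binary-tournament parents.  The run stops at the generation
budget or after a stall window with no improvement of the best overall
score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .evaluation import (DEFAULT_SPLIT_CAP, CVPlan, EvaluatedSolution,
                         evaluate_solution, make_cv_plan)
from .genome import (Chromosome, HyperparamBounds, MutationRates, crossover,
                     init_population, mutate)
from .pareto import DEFAULT_SIGMA_SHARE, ParetoRanking, rank_population
from .prescreen import PrescreenIndex, build_prescreen_index


@dataclass
class RunConfig:
    population_size: int = 50
    max_generations: int = 100
    stall_generations: int = 20
    crossover_prob: float = 0.9
    mutation: MutationRates = field(default_factory=MutationRates)
    elite_fraction: float = 0.5  # cap on front-0 elites, as fraction of population
    base_seed: int = 0
    weights: np.ndarray | None = None  # objective weights for weighted_overall
    bounds: HyperparamBounds = field(default_factory=HyperparamBounds)
    k_folds: int = 10
    sigma_share: float = DEFAULT_SIGMA_SHARE
    split_cap: float = DEFAULT_SPLIT_CAP
    stall_tol: float = 1e-6

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for name in ("crossover_prob", "elite_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class RunState:
    generation: int
    population: list[EvaluatedSolution]
    ranking: ParetoRanking
    best_history: list[float]
    rng: np.random.Generator


@dataclass
class RunResult:
    population: list[EvaluatedSolution]
    ranking: ParetoRanking
    best_history: list[float]
    generations_run: int
    stopped_by: str
    front0: list[EvaluatedSolution]

    def front0_hash(self) -> str:
        import hashlib
        payload = json.dumps([s.chromosome.to_dict() for s in self.front0],
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def select_parents(population: list[EvaluatedSolution], ranking: ParetoRanking,
                   n_pairs: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Binary-tournament parent pairs.

    Candidates are compared by lower front index, then higher niched score,
    then lower chromosome hash (a deterministic final tiebreak).
    """
    n = len(population)
    if n < 2:
        raise ValueError("need at least 2 solutions to select parents")

    def key(i: int):
        return (ranking.front_index[i], -ranking.niched_score[i],
                population[i].chromosome.stable_hash())

    def tournament() -> int:
        i, j = rng.integers(n), rng.integers(n)
        return i if key(i) <= key(j) else j

    return [(tournament(), tournament()) for _ in range(n_pairs)]


def _evaluate_population(chroms: list[Chromosome], dataset, index, plan: CVPlan,
                         config: RunConfig,
                         cache: dict[str, EvaluatedSolution]) -> list[EvaluatedSolution]:
    out = []
    for c in chroms:
        h = c.stable_hash()
        if h not in cache:  # cache is per-generation: the CV plan changes each step
            cache[h] = evaluate_solution(c, dataset, index, plan, config.bounds,
                                         config.weights, config.split_cap)
        out.append(cache[h])
    return out


def init_state(config: RunConfig, dataset, index: PrescreenIndex) -> RunState:
    rng = np.random.default_rng(config.base_seed)
    chroms = init_population(dataset.n_features, config.population_size,
                             config.bounds, rng)
    plan = make_cv_plan(dataset.y, config.k_folds, config.base_seed, 0)
    population = _evaluate_population(chroms, dataset, index, plan, config, {})
    ranking = rank_population(population, config.bounds, config.sigma_share)
    best = max(s.overall for s in population)
    return RunState(generation=0, population=population, ranking=ranking,
                    best_history=[best], rng=rng)


def step_generation(state: RunState, config: RunConfig, dataset,
                    index: PrescreenIndex) -> RunState:
    """Advance one generation; the population size stays constant."""
    pop, ranking, rng = state.population, state.ranking, state.rng
    size = config.population_size
    # elites: first front ordered by niched score, capped
    cap = max(1, int(config.elite_fraction * size))
    front0 = sorted(ranking.fronts[0], key=lambda i: (-ranking.niched_score[i], i))
    elite_idx = front0[:cap]
    # ensure the best-overall solution survives verbatim (monotone history)
    best_i = int(np.argmax([s.overall for s in pop]))
    if best_i not in elite_idx:
        elite_idx = [best_i] + elite_idx[: cap - 1]
    next_chroms = [pop[i].chromosome.copy() for i in elite_idx]

    n_needed = size - len(next_chroms)
    pairs = select_parents(pop, ranking, (n_needed + 1) // 2, rng)
    offspring: list[Chromosome] = []
    for i, j in pairs:
        a, b = pop[i].chromosome, pop[j].chromosome
        if rng.random() < config.crossover_prob:
            c1, c2 = crossover(a, b, rng)
        else:
            c1, c2 = a.copy(), b.copy()
        offspring.append(mutate(c1, config.mutation, config.bounds, rng))
        offspring.append(mutate(c2, config.mutation, config.bounds, rng))
    next_chroms.extend(offspring[:n_needed])

    gen = state.generation + 1
    plan = make_cv_plan(dataset.y, config.k_folds, config.base_seed, gen)
    population = _evaluate_population(next_chroms, dataset, index, plan, config, {})
    ranking = rank_population(population, config.bounds, config.sigma_share)
    best = max(max(s.overall for s in population), state.best_history[-1])
    return RunState(generation=gen, population=population, ranking=ranking,
                    best_history=state.best_history + [best], rng=rng)


def run(config: RunConfig, dataset, index: PrescreenIndex | None = None,
        log=None) -> RunResult:
    """Run the evolutionary search until a stop criterion fires.

    Stops at ``max_generations`` or when the best overall score has not
    improved by more than ``stall_tol`` for ``stall_generations``
    consecutive generations.  Returns the final population with its
    recomputed ranking and the front-0 solutions.
    """
    if index is None:
        index = build_prescreen_index(dataset, config.bounds.k_max)
    state = init_state(config, dataset, index)
    stopped_by = "budget"
    stall = 0
    for _ in range(config.max_generations):
        prev_best = state.best_history[-1]
        state = step_generation(state, config, dataset, index)
        improved = state.best_history[-1] > prev_best + config.stall_tol
        stall = 0 if improved else stall + 1
        if log is not None:
            overalls = [s.overall for s in state.population]
            log(f"gen {state.generation:3d}  best {max(overalls):.4f}  "
                f"median {np.median(overalls):.4f}  "
                f"front0 {len(state.ranking.fronts[0])}  "
                f"mean_active {np.mean([s.n_active_features for s in state.population]):.1f}")
        if stall >= config.stall_generations:
            stopped_by = "stall"
            break
    ranking = rank_population(state.population, config.bounds, config.sigma_share)
    front0 = [state.population[i] for i in ranking.fronts[0]]
    return RunResult(population=state.population, ranking=ranking,
                     best_history=state.best_history,
                     generations_run=state.generation, stopped_by=stopped_by,
                     front0=front0)
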