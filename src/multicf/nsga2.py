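"""Elitist non-dominated-sorting genetic algorithm over a mixed-type genome.

The search space is the unioned feature space: continuous genes move under
simulated binary crossover (SBX) and polynomial mutation, binary/categorical
genes under uniform exchange and uniform re-draw, and user-fixed genes never
move at all. Fitness is the vector of per-disease predicted probabilities
(all minimised); selection is the classic crowded-comparison tournament and
the next generation is the best N of parents plus offspring by (front rank,
crowding distance) — so the per-objective minimum can never increase.

Non-dominated sorting uses a vectorised pairwise-domination matrix, which is
what keeps population sizes in the hundreds cheap; the test suite checks it
against an O(n^2) pure-Python oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ContractViolationError
from .feature_space import (
    CONTINUOUS,
    FeatureUnion,
    ResolvedBound,
    UserConstraints,
    genome_to_frame,
    resolve_bounds,
)
from .risk_models import RiskModel


@dataclass
class Individual:
    """One candidate solution: a full gene vector over the union."""

    genome: np.ndarray
    objectives: np.ndarray | None = None
    rank: int | None = None
    crowding: float | None = None

    def copy(self) -> "Individual":
        return Individual(
            genome=self.genome.copy(),
            objectives=None if self.objectives is None else self.objectives.copy(),
            rank=self.rank,
            crowding=self.crowding,
        )


@dataclass
class Population:
    members: list[Individual]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def objective_matrix(self) -> np.ndarray:
        if any(m.objectives is None for m in self.members):
            raise RuntimeError("population contains unevaluated members")
        return np.vstack([m.objectives for m in self.members])


@dataclass(frozen=True)
class OptimizerConfig:
    """Search hyper-parameters; defaults are the canonical NSGA-II suite."""

    population_size: int = 100
    max_generations: int = 40
    crossover_probability: float = 0.9
    mutation_probability: float | None = None  # None -> 1/k per gene
    sbx_eta: float = 15.0
    mutation_eta: float = 20.0
    tournament_size: int = 2
    seed: int = 0
    early_stop_generations: int | None = None  # off by default

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ConfigurationError("population_size must be even and >= 4")
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be >= 1")
        for p in (self.crossover_probability, self.mutation_probability):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")


class GenomeSpace:
    """Array view of the resolved bounds, fixing the gene layout."""

    def __init__(self, union: FeatureUnion, bounds: Mapping[str, ResolvedBound]):
        self.union = union
        self.names = union.names
        k = union.k
        self.lower = np.empty(k)
        self.upper = np.empty(k)
        self.is_fixed = np.zeros(k, dtype=bool)
        self.is_continuous = np.zeros(k, dtype=bool)
        self.n_choices = np.zeros(k, dtype=int)
        for i, spec in enumerate(union.features):
            b = bounds[spec.name]
            self.lower[i], self.upper[i] = b.lower, b.upper
            self.is_fixed[i] = b.is_fixed
            self.is_continuous[i] = spec.kind == CONTINUOUS
            if spec.kind != CONTINUOUS:
                self.n_choices[i] = spec.n_choices
            if not b.is_fixed and b.lower > b.upper:
                raise ConfigurationError(
                    f"free feature {spec.name!r} has lower > upper after resolution"
                )
        self.free = np.flatnonzero(~self.is_fixed)
        self.k = k

    def clip(self, genome: np.ndarray) -> np.ndarray:
        out = np.clip(genome, self.lower, self.upper)
        disc = ~self.is_continuous
        out[disc] = np.round(out[disc])
        out[self.is_fixed] = self.lower[self.is_fixed]
        return out


# ---------------------------------------------------------------------------
# population construction and evaluation


def initialize_population(space: GenomeSpace, n: int, rng: np.random.Generator) -> Population:
    """Uniform random population inside the resolved bounds; fixed genes pinned."""
    genomes = np.empty((n, space.k))
    for i in range(space.k):
        if space.is_fixed[i]:
            genomes[:, i] = space.lower[i]
        elif space.is_continuous[i]:
            genomes[:, i] = rng.uniform(space.lower[i], space.upper[i], size=n)
        else:
            genomes[:, i] = rng.integers(
                int(space.lower[i]), int(space.upper[i]) + 1, size=n
            ).astype(float)
    return Population([Individual(genomes[j]) for j in range(n)], generation=0)


def evaluate(
    population: Population,
    models: Sequence[RiskModel],
    union: FeatureUnion,
) -> Population:
    """Score every member against every disease model (batched per model)."""
    if not models:
        raise ValueError("need at least one risk model")
    todo = [m for m in population.members if m.objectives is None]
    if not todo:
        return population
    genomes = np.vstack([m.genome for m in todo])
    decoded = genome_to_frame(union, genomes)
    objective_cols = []
    for model in models:
        frame = decoded[list(model.feature_order)]
        probs = model.predict_frame(frame)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ContractViolationError(
                f"model for {model.disease!r} returned probability outside [0, 1]"
            )
        objective_cols.append(probs)
    objectives = np.column_stack(objective_cols)
    for j, member in enumerate(todo):
        member.objectives = objectives[j]
    return population


# ---------------------------------------------------------------------------
# dominance machinery


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Minimisation dominance: a <= b everywhere and a < b somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(a <= b) and np.any(a < b))


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """D[i, j] = True iff member i dominates member j (vectorised)."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    return le & lt


def fast_non_dominated_sort(population: Population) -> list[list[int]]:
    """Partition members into successive non-dominated fronts.

    Sets each member's ``rank`` to its front index and returns the fronts as
    lists of member indices.
    """
    F = population.objective_matrix()
    D = _domination_matrix(F)
    n_dom = D.sum(axis=0)  # how many members dominate j
    fronts: list[list[int]] = []
    remaining = np.ones(len(F), dtype=bool)
    while remaining.any():
        current = np.flatnonzero(remaining & (n_dom == 0))
        if current.size == 0:  # cannot happen with a strict partial order
            raise RuntimeError("non-dominated sort failed to make progress")
        fronts.append(current.tolist())
        remaining[current] = False
        n_dom = n_dom - D[current].sum(axis=0)
    for r, front in enumerate(fronts):
        for i in front:
            population.members[i].rank = r
    return fronts


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Per-member crowding distance within one front.

    Boundary members on any objective get +inf; interior members accumulate
    normalised nearest-neighbour gaps; a zero objective range contributes 0.
    """
    F = np.atleast_2d(np.asarray(front_objectives, dtype=float))
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        vals = F[order, j]
        span = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            gaps = (vals[2:] - vals[:-2]) / span
            interior = order[1:-1]
            finite = np.isfinite(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def _assign_crowding(population: Population, fronts: list[list[int]]) -> None:
    F = population.objective_matrix()
    for front in fronts:
        d = crowding_distance(F[front])
        for i, idx in enumerate(front):
            population.members[idx].crowding = float(d[i])


def sort_population(population: Population) -> list[list[int]]:
    """Rank + crowding in one pass (Algorithm's 'rank and apply crowding')."""
    fronts = fast_non_dominated_sort(population)
    _assign_crowding(population, fronts)
    return fronts


# ---------------------------------------------------------------------------
# variation


def _crowded_winner(
    i: int, j: int, members: list[Individual], rng: np.random.Generator
) -> int:
    a, b = members[i], members[j]
    if a.rank != b.rank:
        return i if a.rank < b.rank else j
    if a.crowding != b.crowding:
        return i if a.crowding > b.crowding else j
    return i if rng.random() < 0.5 else j


def _tournament(
    members: list[Individual], size: int, rng: np.random.Generator
) -> int:
    pick = int(rng.integers(len(members)))
    for _ in range(size - 1):
        rival = int(rng.integers(len(members)))
        pick = _crowded_winner(pick, rival, members, rng)
    return pick


def _sbx_pair(
    x1: float, x2: float, lo: float, hi: float, eta: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Simulated binary crossover for one gene (bounded, Deb & Agrawal)."""
    if abs(x1 - x2) < 1e-14 or lo == hi:
        return x1, x2
    y1, y2 = (x1, x2) if x1 < x2 else (x2, x1)
    u = rng.random()
    beta = 1.0 + (2.0 * (y1 - lo) / (y2 - y1))
    alpha = 2.0 - beta ** (-(eta + 1.0))
    if u <= 1.0 / alpha:
        betaq = (u * alpha) ** (1.0 / (eta + 1.0))
    else:
        betaq = (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
    c1 = 0.5 * ((y1 + y2) - betaq * (y2 - y1))
    beta = 1.0 + (2.0 * (hi - y2) / (y2 - y1))
    alpha = 2.0 - beta ** (-(eta + 1.0))
    if u <= 1.0 / alpha:
        betaq = (u * alpha) ** (1.0 / (eta + 1.0))
    else:
        betaq = (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
    c2 = 0.5 * ((y1 + y2) + betaq * (y2 - y1))
    c1, c2 = min(max(c1, lo), hi), min(max(c2, lo), hi)
    if rng.random() < 0.5:
        c1, c2 = c2, c1
    return (c1, c2) if x1 < x2 else (c2, c1)


def _polynomial_mutation(
    x: float, lo: float, hi: float, eta: float, rng: np.random.Generator
) -> float:
    """Bounded polynomial mutation for one gene."""
    if hi <= lo:
        return x
    delta1 = (x - lo) / (hi - lo)
    delta2 = (hi - x) / (hi - lo)
    u = rng.random()
    mut_pow = 1.0 / (eta + 1.0)
    if u < 0.5:
        xy = 1.0 - delta1
        val = 2.0 * u + (1.0 - 2.0 * u) * xy ** (eta + 1.0)
        deltaq = val ** mut_pow - 1.0
    else:
        xy = 1.0 - delta2
        val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * xy ** (eta + 1.0)
        deltaq = 1.0 - val ** mut_pow
    return min(max(x + deltaq * (hi - lo), lo), hi)


def make_offspring(
    population: Population,
    config: OptimizerConfig,
    space: GenomeSpace,
    rng: np.random.Generator,
) -> Population:
    """Produce N offspring by tournament selection + crossover + mutation.

    Continuous free genes: SBX and polynomial mutation. Discrete free genes:
    uniform exchange and uniform re-draw. Fixed genes are copied verbatim
    and never touched by any operator.
    """
    members = population.members
    n = config.population_size
    pm = (
        config.mutation_probability
        if config.mutation_probability is not None
        else (1.0 / max(len(space.free), 1))
    )
    children: list[Individual] = []
    while len(children) < n:
        p1 = members[_tournament(members, config.tournament_size, rng)]
        p2 = members[_tournament(members, config.tournament_size, rng)]
        c1, c2 = p1.genome.copy(), p2.genome.copy()
        if rng.random() < config.crossover_probability:
            for i in space.free:
                if space.is_continuous[i]:
                    if rng.random() < 0.5:
                        c1[i], c2[i] = _sbx_pair(
                            c1[i], c2[i], space.lower[i], space.upper[i],
                            config.sbx_eta, rng,
                        )
                else:
                    if rng.random() < 0.5:
                        c1[i], c2[i] = c2[i], c1[i]
        for child in (c1, c2):
            for i in space.free:
                if rng.random() < pm:
                    if space.is_continuous[i]:
                        child[i] = _polynomial_mutation(
                            child[i], space.lower[i], space.upper[i],
                            config.mutation_eta, rng,
                        )
                    else:
                        child[i] = float(
                            rng.integers(int(space.lower[i]), int(space.upper[i]) + 1)
                        )
        children.append(Individual(space.clip(c1)))
        if len(children) < n:
            children.append(Individual(space.clip(c2)))
    return Population(children, generation=population.generation + 1)


# ---------------------------------------------------------------------------
# environmental selection and the main loop


def environmental_select(combined: Population, n: int) -> Population:
    """Keep the best ``n`` of parents + offspring by (rank, crowding).

    Whole fronts are admitted in rank order; the straddling front is
    truncated by descending crowding distance with stable index tie-break.
    """
    if n > len(combined):
        raise ValueError(f"cannot select {n} from a population of {len(combined)}")
    fronts = sort_population(combined)
    chosen: list[Individual] = []
    for front in fronts:
        if len(chosen) + len(front) <= n:
            chosen.extend(combined.members[i] for i in front)
        else:
            room = n - len(chosen)
            by_crowding = sorted(
                front, key=lambda i: (-combined.members[i].crowding, i)
            )
            chosen.extend(combined.members[i] for i in by_crowding[:room])
        if len(chosen) == n:
            break
    return Population([m.copy() for m in chosen], generation=combined.generation)


@dataclass
class RunResult:
    """Final state of one optimisation run."""

    population: Population
    front: list[Individual]
    trace: pd.DataFrame
    objective_names: tuple[str, ...]
    seed: int


def run(
    models: Sequence[RiskModel],
    union: FeatureUnion,
    constraints: UserConstraints | None,
    config: OptimizerConfig,
    window_fraction: float = 0.10,
    penalty_fn: Callable[[np.ndarray], float] | None = None,
    callback: Callable[[int, Population], None] | None = None,
) -> RunResult:
    """Full elitist loop: init -> evaluate -> (offspring, combine, select)*.

    The trace records, per generation, the minimum of each objective over the
    current population and the minimum penalty (if ``penalty_fn`` is given) —
    the raw material for convergence plots. Deterministic for a fixed
    ``config.seed``.
    """
    bounds = resolve_bounds(union, constraints, window_fraction)
    space = GenomeSpace(union, bounds)
    rng = np.random.default_rng(config.seed)
    names = tuple(m.disease for m in models)

    pop = initialize_population(space, config.population_size, rng)
    evaluate(pop, models, union)
    sort_population(pop)

    rows: list[dict] = []

    def record(gen: int, population: Population) -> None:
        F = population.objective_matrix()
        row: dict = {"generation": gen}
        for j, name in enumerate(names):
            row[f"min_{name}"] = float(F[:, j].min())
        if penalty_fn is not None:
            row["min_penalty"] = float(min(penalty_fn(f) for f in F))
        rows.append(row)
        if callback is not None:
            callback(gen, population)

    record(0, pop)
    stall = 0
    best_prev = pop.objective_matrix().min(axis=0)
    for gen in range(1, config.max_generations + 1):
        offspring = make_offspring(pop, config, space, rng)
        if not offspring.members:
            raise RuntimeError(f"generation {gen} produced no valid offspring")
        evaluate(offspring, models, union)
        combined = Population(
            [m.copy() for m in pop.members] + offspring.members, generation=gen
        )
        pop = environmental_select(combined, config.population_size)
        record(gen, pop)
        best_now = pop.objective_matrix().min(axis=0)
        if config.early_stop_generations is not None:
            stall = 0 if np.any(best_now < best_prev - 1e-15) else stall + 1
            if stall >= config.early_stop_generations:
                break
        best_prev = best_now

    fronts = sort_population(pop)
    front = [pop.members[i] for i in fronts[0]]
    return RunResult(
        population=pop,
        front=front,
        trace=pd.DataFrame(rows),
        objective_names=names,
        seed=config.seed,
    )
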