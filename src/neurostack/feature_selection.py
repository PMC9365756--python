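"""Wrapper feature selection by GA / NSGA-II.

A genotype is scored by repeated stratified cross-validation of a classifier
trained on just its columns (fitness 1); the parsimony objective is
``1 - Length(Individual) / Num. Features`` (fitness 2). Results are cached
per feature set, evolution is fully reproducible per seed, and independent
restarts are merged into a single non-dominated front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import ClassifierSpec, cv_score
from .datamodel import ConfigurationError, Dataset, FeatureSpace
from .evo_core import (
    ContractError,
    ConvergenceTrace,
    Individual,
    ParetoFront,
    pareto_filter,
    run_ga,
    run_nsga2,
)


@dataclass
class FitnessSpec:
    """CV protocol for the performance objective: 5 repeats of stratified 5-CV."""

    metric: str = "accuracy"
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("bernoulli_nb"))
    cv_folds: int = 5
    cv_repeats: int = 5

    def __post_init__(self) -> None:
        if self.metric not in ("accuracy", "f1"):
            raise ConfigurationError("metric must be accuracy or f1")
        if self.cv_repeats < 1:
            raise ConfigurationError("cv_repeats must be >= 1")


@dataclass
class EvolutionConfig:
    """Engine settings. Population size and generation count are tool
    defaults (100/200); the search itself uses tournament selection (k=2)
    and random-resetting mutation, with 2 independent restarts whose final
    fronts are merged by non-domination."""

    population_size: int = 100
    generations: int = 200
    p_crossover: float = 0.9
    p_mutation: float | None = None  # default: 1/length per gene
    max_init_length: int | None = None  # default: num_features // 2
    restarts: int = 2
    seed: int = 0
    survivor_strategy: str = "elitism"
    elite: int = 1
    annihilate: int = 1


@dataclass
class SubsetSolution:
    genotype: np.ndarray
    fitness1: float
    fitness2: float
    selected_names: list[str]


def fitness2(genotype: Individual | np.ndarray, space: FeatureSpace) -> float:
    """Parsimony objective: 1 - Length(Individual) / Num. Features."""
    g = genotype.genotype if isinstance(genotype, Individual) else np.asarray(genotype)
    if g.size == 0:
        raise ContractError("empty genotype")
    if g.size > space.num_features:
        raise ContractError("genotype longer than the feature space")
    return 1.0 - g.size / space.num_features


class _FitnessCache:
    """Memoize CV scores per feature set; wrapper search re-evaluates
    duplicate subsets heavily and the score is a pure function of the set."""

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: FitnessSpec, seed: int):
        self.X, self.y, self.spec, self.seed = X, y, spec, seed
        self.cache: dict[frozenset, float] = {}

    def __call__(self, ind: Individual) -> float:
        key = ind.key()
        if key not in self.cache:
            cols = np.asarray(sorted(key), dtype=int)
            self.cache[key] = cv_score(
                self.spec.classifier,
                self.X[:, cols],
                self.y,
                metric=self.spec.metric,
                cv_folds=self.spec.cv_folds,
                cv_repeats=self.spec.cv_repeats,
                seed=self.seed,
            )
        return self.cache[key]


def fitness1(genotype: Individual, data: Dataset, spec: FitnessSpec, seed: int = 0) -> float:
    """Mean held-out metric of the classifier on the genotype's columns."""
    X = data.numeric_matrix()
    y = data.y.to_numpy()
    return _FitnessCache(X, y, spec, seed)(genotype)


def _front_to_solutions(front: ParetoFront, names: list[str]) -> list[SubsetSolution]:
    out = []
    for (f1, f2), g in front.points:
        out.append(SubsetSolution(g, f1, f2, [names[i] for i in g]))
    return out


def run_nsga2_selection(
    data: Dataset,
    fitness_spec: FitnessSpec | None = None,
    cfg: EvolutionConfig | None = None,
) -> tuple[ParetoFront, list[SubsetSolution], list[ConvergenceTrace]]:
    """Bi-objective wrapper selection: CV performance vs. parsimony.

    Runs ``cfg.restarts`` independent NSGA-II searches with distinct seeds
    and merges the final fronts by non-domination.
    """
    fitness_spec = fitness_spec or FitnessSpec()
    cfg = cfg or EvolutionConfig()
    space = data.feature_space()
    X = data.numeric_matrix()
    y = data.y.to_numpy()
    cache = _FitnessCache(X, y, fitness_spec, cfg.seed)

    def evaluate(ind: Individual) -> tuple[float, float]:
        return cache(ind), fitness2(ind, space)

    all_points: list = []
    traces: list[ConvergenceTrace] = []
    for r in range(cfg.restarts):
        front, trace = run_nsga2(
            evaluate,
            space.num_features,
            cfg.population_size,
            cfg.generations,
            seed=cfg.seed + 1000 * r,
            p_crossover=cfg.p_crossover,
            p_mutation=cfg.p_mutation,
            max_init_length=cfg.max_init_length,
        )
        trace.restart = r
        traces.append(trace)
        all_points += front.points
    merged = ParetoFront(pareto_filter(all_points), (0.0, 0.0))
    return merged, _front_to_solutions(merged, space.names), traces


def run_ga_selection(
    data: Dataset,
    fitness_spec: FitnessSpec | None = None,
    cfg: EvolutionConfig | None = None,
) -> tuple[SubsetSolution, ConvergenceTrace]:
    """Mono-objective GA on CV performance; elitism keeps the best alive."""
    fitness_spec = fitness_spec or FitnessSpec()
    cfg = cfg or EvolutionConfig()
    space = data.feature_space()
    X = data.numeric_matrix()
    y = data.y.to_numpy()
    cache = _FitnessCache(X, y, fitness_spec, cfg.seed)
    best, trace = run_ga(
        cache,
        space.num_features,
        cfg.population_size,
        cfg.generations,
        seed=cfg.seed,
        survivor_strategy=cfg.survivor_strategy,
        e=cfg.elite,
        a=cfg.annihilate,
        p_crossover=cfg.p_crossover,
        p_mutation=cfg.p_mutation,
        max_init_length=cfg.max_init_length,
    )
    sol = SubsetSolution(
        best.genotype,
        best.fitness[0],
        fitness2(best, space),
        [space.names[i] for i in best.genotype],
    )
    return sol, trace
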