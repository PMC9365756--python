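"""Generic evolutionary machinery.

Genotypes are variable-length, duplicate-free integer arrays indexing a
feature space. All objectives are maximized. Provides selection, variation
and survivor operators, a mono-objective GA loop, NSGA-II (non-dominated
sorting + crowding distance) and the hypervolume indicator computed by
inclusion-exclusion over axis-aligned boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np


class ContractError(ValueError):
    pass


@dataclass
class Individual:
    """A candidate feature subset: ordered, duplicate-free indices."""

    genotype: np.ndarray
    fitness: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=int)
        if self.genotype.size == 0:
            raise ContractError("genotype must be non-empty")
        if len(set(self.genotype.tolist())) != self.genotype.size:
            raise ContractError("genotype must be duplicate-free")

    def key(self) -> frozenset:
        return frozenset(self.genotype.tolist())

    def copy(self) -> "Individual":
        return Individual(self.genotype.copy(), self.fitness)


@dataclass
class ParetoFront:
    """Mutually non-dominated (objective1, objective2) points with genotypes."""

    points: list[tuple[tuple[float, ...], np.ndarray]]
    reference_point: tuple[float, ...] = (0.0, 0.0)

    def objectives(self) -> list[tuple[float, ...]]:
        return [p[0] for p in self.points]

    def to_dict(self) -> dict:
        return {
            "points": [
                {"objectives": list(obj), "genotype": np.asarray(g).tolist()}
                for obj, g in self.points
            ],
            "reference_point": list(self.reference_point),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParetoFront":
        pts = [(tuple(p["objectives"]), np.asarray(p["genotype"], dtype=int)) for p in d["points"]]
        return cls(pts, tuple(d["reference_point"]))


from .datamodel import register_artifact  # noqa: E402

register_artifact("pareto_front")(ParetoFront)


# ---------------------------------------------------------------------------
# Dominance, sorting, crowding
# ---------------------------------------------------------------------------


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Strict Pareto dominance under maximization."""
    if len(a) != len(b):
        raise ContractError("objective tuples must have equal arity")
    ge = all(x >= y for x, y in zip(a, b))
    gt = any(x > y for x, y in zip(a, b))
    return ge and gt


def non_dominated_sort(objectives: Sequence[Sequence[float]]) -> list[list[int]]:
    """Fast non-dominated sorting; front 0 is the maximal non-dominated set."""
    n = len(objectives)
    for o in objectives:
        if o is None:
            raise ContractError("all individuals must be evaluated")
    S: list[list[int]] = [[] for _ in range(n)]
    dominated_count = np.zeros(n, dtype=int)
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objectives[i], objectives[j]):
                S[i].append(j)
                dominated_count[j] += 1
            elif dominates(objectives[j], objectives[i]):
                S[j].append(i)
                dominated_count[i] += 1
    for i in range(n):
        if dominated_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in S[i]:
                dominated_count[j] -= 1
                if dominated_count[j] == 0:
                    nxt.append(j)
        k += 1
        fronts.append(nxt)
    return [f for f in fronts if f]


def crowding_distance(front: Sequence[Sequence[float]]) -> list[float]:
    """NSGA-II crowding distance; boundary points get +inf per objective."""
    n = len(front)
    if n == 0:
        raise ContractError("front must be non-empty")
    m = len(front[0])
    dist = np.zeros(n)
    for k in range(m):
        vals = np.array([f[k] for f in front], dtype=float)
        order = np.argsort(vals, kind="stable")
        rng = vals[order[-1]] - vals[order[0]]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng == 0:
            continue
        for idx in range(1, n - 1):
            i = order[idx]
            if not np.isinf(dist[i]):
                dist[i] += (vals[order[idx + 1]] - vals[order[idx - 1]]) / rng
    return dist.tolist()


def pareto_filter(points: list[tuple[tuple[float, ...], np.ndarray]]) -> list:
    """Keep the non-dominated subset (first occurrence wins duplicates)."""
    kept = []
    seen = set()
    objs = [p[0] for p in points]
    for i, (obj, g) in enumerate(points):
        if any(dominates(objs[j], obj) for j in range(len(points)) if j != i):
            continue
        tag = (obj, tuple(np.asarray(g).tolist()))
        if tag in seen:
            continue
        seen.add(tag)
        kept.append((obj, np.asarray(g)))
    return kept


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select(
    pop: list[Individual],
    n_parents: int,
    rng: np.random.Generator,
    strategy: str = "tournament",
    k: int = 2,
) -> list[Individual]:
    """Parent selection: binary tournament (without replacement within a
    tournament) or fitness-proportional roulette."""
    if strategy == "tournament":
        out = []
        for _ in range(n_parents):
            if len(pop) == 1:
                out.append(pop[0])
                continue
            idx = rng.choice(len(pop), size=min(k, len(pop)), replace=False)
            best = max(idx, key=lambda i: pop[i].fitness)
            out.append(pop[best])
        return out
    if strategy == "fitness_proportional":
        w = np.array([p.fitness[0] for p in pop], dtype=float)
        if (w < 0).any():
            raise ContractError("fitness_proportional needs nonnegative fitness")
        if w.sum() == 0:
            import warnings

            warnings.warn("all-zero fitness: falling back to uniform selection", stacklevel=2)
            w = np.ones_like(w)
        p = w / w.sum()
        idx = rng.choice(len(pop), size=n_parents, p=p)
        return [pop[i] for i in idx]
    raise ContractError(f"unknown selection strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Variation
# ---------------------------------------------------------------------------


def _dedup(arr: np.ndarray) -> np.ndarray:
    seen: set[int] = set()
    out = []
    for g in arr.tolist():
        if g not in seen:
            seen.add(g)
            out.append(g)
    return np.array(out, dtype=int)


def one_point_crossover(
    a: Individual, b: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Variable-length one-point crossover with per-parent cut points.

    Offspring are deduplicated (a duplicated feature index is meaningless
    for subset selection), shrinking the genotype where needed.
    """
    ca = int(rng.integers(0, a.genotype.size)) if a.genotype.size > 1 else 0
    cb = int(rng.integers(0, b.genotype.size)) if b.genotype.size > 1 else 0
    g1 = _dedup(np.concatenate([a.genotype[: ca + 1], b.genotype[cb + 1 :]]))
    g2 = _dedup(np.concatenate([b.genotype[: cb + 1], a.genotype[ca + 1 :]]))
    if g1.size == 0:
        g1 = a.genotype[:1].copy()
    if g2.size == 0:
        g2 = b.genotype[:1].copy()
    return Individual(g1), Individual(g2)


def random_resetting(
    ind: Individual, num_features: int, rng: np.random.Generator, p: float | None = None
) -> Individual:
    """Replace each gene (with prob p, default 1/length) by an unused index."""
    g = ind.genotype.copy()
    if p is None:
        p = 1.0 / g.size
    for i in range(g.size):
        if rng.random() < p:
            unused = np.setdiff1d(np.arange(num_features), g)
            if unused.size:
                g[i] = unused[rng.integers(0, unused.size)]
    return Individual(_dedup(g))


def vary(
    parents: list[Individual],
    num_features: int,
    rng: np.random.Generator,
    p_crossover: float = 0.9,
    p_mutation: float | None = None,
) -> list[Individual]:
    """Pairwise one-point crossover followed by random-resetting mutation."""
    offspring: list[Individual] = []
    for i in range(0, len(parents) - 1, 2):
        a, b = parents[i], parents[i + 1]
        if rng.random() < p_crossover:
            c1, c2 = one_point_crossover(a, b, rng)
        else:
            c1, c2 = a.copy(), b.copy()
        offspring += [c1, c2]
    if len(parents) % 2:
        offspring.append(parents[-1].copy())
    return [random_resetting(o, num_features, rng, p_mutation) for o in offspring]


def survivors(
    pop: list[Individual],
    offspring: list[Individual],
    strategy: str = "elitism",
    e: int = 1,
    a: int = 1,
) -> list[Individual]:
    """Survivor selection restoring the parent population size.

    ``elitism``: the e best parents survive unconditionally, the rest of the
    next generation comes from the best offspring. ``annihilation``: the a
    worst parents are deleted and refilled from the best offspring.
    """
    size = len(pop)
    ranked_par = sorted(pop, key=lambda i: i.fitness, reverse=True)
    ranked_off = sorted(offspring, key=lambda i: i.fitness, reverse=True)
    if strategy == "elitism":
        if e >= size:
            raise ContractError("e must be < population size")
        need = size - e
        if need > len(ranked_off):
            raise ContractError("not enough offspring to refill population")
        return ranked_par[:e] + ranked_off[:need]
    if strategy == "annihilation":
        if a >= size:
            raise ContractError("a must be < population size")
        if a > len(ranked_off):
            raise ContractError("not enough offspring to refill population")
        keep = ranked_par[: size - a]
        return keep + ranked_off[:a]
    raise ContractError(f"unknown survivor strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Hypervolume (inclusion-exclusion)
# ---------------------------------------------------------------------------

MAX_HV_POINTS = 20


def hypervolume(front: ParetoFront) -> float:
    """Hypervolume indicator I_H relative to the reference point.

    The dominated region is the union of axis-aligned boxes
    [reference, point]; its volume — the d-dimensional volume of the
    hole-free orthogonal polytope spanned by the front — is computed by
    inclusion-exclusion over point subsets (the intersection of boxes is
    the box of componentwise minima). Exponential in the number of points;
    fronts are capped at 20 points, ample for bi-objective fronts here.
    """
    ref = np.asarray(front.reference_point, dtype=float)
    pts = np.asarray([p[0] for p in front.points], dtype=float)
    if pts.size == 0:
        return 0.0
    if (pts < ref).any() or (pts == ref).all(axis=1).any():
        raise ContractError("every point must dominate the reference point")
    if len(pts) > MAX_HV_POINTS:
        raise ContractError(
            f"inclusion-exclusion capped at {MAX_HV_POINTS} points; "
            "sweep-based algorithms are the optimization hook for larger fronts"
        )
    n = len(pts)
    total = 0.0
    for r in range(1, n + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for subset in combinations(range(n), r):
            mins = pts[list(subset)].min(axis=0)
            total += sign * float(np.prod(mins - ref))
    return total


# ---------------------------------------------------------------------------
# Evolution loops
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceTrace:
    """Per-generation best/mean of each objective, per restart."""

    restart: int = 0
    generations: list[dict] = field(default_factory=list)

    def record(self, gen: int, objectives: Sequence[Sequence[float]]) -> None:
        arr = np.asarray(objectives, dtype=float)
        self.generations.append(
            {
                "generation": gen,
                "best": arr.max(axis=0).tolist(),
                "mean": arr.mean(axis=0).tolist(),
            }
        )

    def best_series(self, objective: int = 0) -> list[float]:
        return [g["best"][objective] for g in self.generations]


def init_population(
    pop_size: int,
    num_features: int,
    rng: np.random.Generator,
    max_init_length: int | None = None,
) -> list[Individual]:
    """Genotype lengths uniform in [1, max_init_length], genes without replacement."""
    L = max_init_length or max(1, num_features // 2)
    L = min(L, num_features)
    pop = []
    for _ in range(pop_size):
        length = int(rng.integers(1, L + 1))
        genes = rng.choice(num_features, size=length, replace=False)
        pop.append(Individual(np.sort(genes)))
    return pop


def run_ga(
    evaluate: Callable[[Individual], float],
    num_features: int,
    pop_size: int,
    generations: int,
    seed: int,
    selection: str = "tournament",
    survivor_strategy: str = "elitism",
    e: int = 1,
    a: int = 1,
    p_crossover: float = 0.9,
    p_mutation: float | None = None,
    max_init_length: int | None = None,
) -> tuple[Individual, ConvergenceTrace]:
    """Mono-objective GA; with elitism the best fitness is non-decreasing."""
    rng = np.random.default_rng(seed)
    pop = init_population(pop_size, num_features, rng, max_init_length)
    for ind in pop:
        ind.fitness = (evaluate(ind),)
    trace = ConvergenceTrace()
    trace.record(0, [i.fitness for i in pop])
    for gen in range(1, generations + 1):
        parents = select(pop, pop_size, rng, strategy=selection)
        offspring = vary(parents, num_features, rng, p_crossover, p_mutation)
        for ind in offspring:
            ind.fitness = (evaluate(ind),)
        pop = survivors(pop, offspring, survivor_strategy, e=e, a=a)
        trace.record(gen, [i.fitness for i in pop])
    best = max(pop, key=lambda i: i.fitness)
    return best, trace


def _nsga2_truncate(pool: list[Individual], size: int) -> list[Individual]:
    fronts = non_dominated_sort([i.fitness for i in pool])
    out: list[Individual] = []
    for fr in fronts:
        if len(out) + len(fr) <= size:
            out += [pool[i] for i in fr]
        else:
            cd = crowding_distance([pool[i].fitness for i in fr])
            order = sorted(range(len(fr)), key=lambda j: cd[j], reverse=True)
            out += [pool[fr[j]] for j in order[: size - len(out)]]
            break
    return out


def _crowded_tournament(
    pool: list[Individual],
    rank: dict[int, int],
    cd: dict[int, float],
    rng: np.random.Generator,
) -> Individual:
    i, j = rng.choice(len(pool), size=2, replace=False) if len(pool) > 1 else (0, 0)
    if rank[i] != rank[j]:
        return pool[i] if rank[i] < rank[j] else pool[j]
    return pool[i] if cd[i] >= cd[j] else pool[j]


def run_nsga2(
    evaluate: Callable[[Individual], tuple[float, float]],
    num_features: int,
    pop_size: int,
    generations: int,
    seed: int,
    p_crossover: float = 0.9,
    p_mutation: float | None = None,
    max_init_length: int | None = None,
    reference_point: tuple[float, float] = (0.0, 0.0),
) -> tuple[ParetoFront, ConvergenceTrace]:
    """Bi-objective NSGA-II with binary tournament on (rank, crowding)."""
    rng = np.random.default_rng(seed)
    pop = init_population(pop_size, num_features, rng, max_init_length)
    for ind in pop:
        ind.fitness = tuple(evaluate(ind))
    trace = ConvergenceTrace()
    trace.record(0, [i.fitness for i in pop])
    for gen in range(1, generations + 1):
        fronts = non_dominated_sort([i.fitness for i in pop])
        rank = {i: r for r, fr in enumerate(fronts) for i in fr}
        cd: dict[int, float] = {}
        for fr in fronts:
            d = crowding_distance([pop[i].fitness for i in fr])
            cd.update({i: d[j] for j, i in enumerate(fr)})
        parents = [_crowded_tournament(pop, rank, cd, rng) for _ in range(pop_size)]
        offspring = vary(parents, num_features, rng, p_crossover, p_mutation)
        for ind in offspring:
            ind.fitness = tuple(evaluate(ind))
        pop = _nsga2_truncate(pop + offspring, pop_size)
        trace.record(gen, [i.fitness for i in pop])
    pts = pareto_filter([(i.fitness, i.genotype) for i in pop])
    return ParetoFront(pts, reference_point), trace
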