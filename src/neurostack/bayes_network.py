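"""Discrete Bayesian networks over binarized layer-1 classifier outputs.

One network is learned per diagnostic class; a new example is assigned the
class whose network gives its (binarized) evidence vector the highest joint
probability. Structure learning is exact: per-node best-parent-set tables
feed a dynamic program over node subsets (sink decomposition), guaranteeing
the globally score-optimal DAG for the node counts used here (<= 12).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import register_artifact
from .evo_core import ContractError


class CapacityError(ValueError):
    pass


MAX_EXACT_NODES = 12


def binarize(meta_row: Sequence[float]) -> np.ndarray:
    """Round each value in [0,1] to the nearest integer, halves up."""
    v = np.asarray(meta_row, dtype=float)
    if ((v < 0) | (v > 1)).any():
        raise ContractError("meta-feature values must lie in [0, 1]")
    return np.clip(np.floor(v + 0.5), 0, 1).astype(int)


# ---------------------------------------------------------------------------
# Decomposable family scores
# ---------------------------------------------------------------------------


def _family_counts(rows: np.ndarray, node: int, parents: tuple[int, ...]) -> np.ndarray:
    """Count table of shape (2^|parents|, 2) for node given parent configs."""
    k = len(parents)
    counts = np.zeros((2**k, 2))
    if k:
        conf = rows[:, list(parents)] @ (1 << np.arange(k - 1, -1, -1))
    else:
        conf = np.zeros(len(rows), dtype=int)
    np.add.at(counts, (conf, rows[:, node]), 1.0)
    return counts


def _family_score(rows: np.ndarray, node: int, parents: tuple[int, ...], score: str) -> float:
    counts = _family_counts(rows, node, parents)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / row_tot), 0.0)
    loglik = float(np.nansum(ll))
    if score == "log_likelihood":
        return loglik
    if score == "bic":
        n_params = 2 ** len(parents)  # one free probability per parent config
        return loglik - 0.5 * np.log(len(rows)) * n_params
    raise ContractError(f"unknown score {score!r}")


def learn_structure(
    rows: Sequence[Sequence[int]] | np.ndarray,
    score: str = "bic",
    max_parents: int = 3,
) -> list[tuple[int, ...]]:
    """Globally score-optimal DAG by exact dynamic programming.

    Best parent sets are precomputed per node over all candidate subsets
    (|parents| <= max_parents), then an order DP over node subsets picks the
    optimal sink decomposition. Ties break toward lexicographically smaller
    parent sets (and smaller sink index), making the result deterministic.
    Returns the parent tuple per node.

    The default score is BIC: raw maximum likelihood always prefers the
    maximally connected DAG, so it defeats structure discovery; plain
    log-likelihood remains selectable.
    """
    rows = np.asarray(rows, dtype=int)
    if rows.ndim != 2 or len(rows) < 1:
        raise ContractError("need at least one complete evidence row")
    n = rows.shape[1]
    if n > MAX_EXACT_NODES:
        raise CapacityError(
            f"exact search supports at most {MAX_EXACT_NODES} nodes; "
            "restrict the node set or lower max_parents"
        )

    nodes = list(range(n))
    # score every candidate family once
    family: list[dict[tuple[int, ...], float]] = []
    for v in nodes:
        cand = [u for u in nodes if u != v]
        fam: dict[tuple[int, ...], float] = {}
        for k in range(min(max_parents, n - 1) + 1):
            for ps in combinations(cand, k):
                fam[ps] = _family_score(rows, v, ps, score)
        family.append(fam)

    # best parent set of v drawn from candidate set S (bitmask over nodes)
    # bps[v][S] = (score, parents); ties -> smaller parent set lexicographically
    def better(a: tuple[float, tuple[int, ...]], b: tuple[float, tuple[int, ...]]) -> bool:
        if a[0] != b[0]:
            return a[0] > b[0]
        return (len(a[1]), a[1]) < (len(b[1]), b[1])

    full = 1 << n
    bps: list[list[tuple[float, tuple[int, ...]]]] = [[(-np.inf, ())] * full for _ in nodes]
    for v in nodes:
        for S in range(full):
            if S & (1 << v):
                continue
            best = (family[v][()], ())
            for ps, sc in family[v].items():
                if ps and all(S & (1 << u) for u in ps):
                    if better((sc, ps), best):
                        best = (sc, ps)
            bps[v][S] = best

    # sink DP: dp[S] = best score of a DAG over the nodes in S
    dp = np.full(full, -np.inf)
    choice: list[tuple[int, tuple[int, ...]] | None] = [None] * full
    dp[0] = 0.0
    for S in range(1, full):
        members = [v for v in nodes if S & (1 << v)]
        for v in members:
            rest = S & ~(1 << v)
            sc, ps = bps[v][rest]
            tot = dp[rest] + sc
            if tot > dp[S] or (
                tot == dp[S]
                and choice[S] is not None
                and (v, ps) < choice[S]
            ):
                dp[S] = tot
                choice[S] = (v, ps)

    parents: list[tuple[int, ...]] = [()] * n
    S = full - 1
    while S:
        v, ps = choice[S]
        parents[v] = ps
        S &= ~(1 << v)
    return parents


def brute_force_structure(
    rows: np.ndarray, score: str = "bic", max_parents: int | None = None
) -> tuple[float, list[tuple[int, ...]]]:
    """Exhaustive all-DAG enumeration (test oracle; feasible for <= 4 nodes).

    Enumerates every acyclic parent-set assignment via topological orders.
    """
    rows = np.asarray(rows, dtype=int)
    n = rows.shape[1]
    cap = max_parents if max_parents is not None else n - 1
    from itertools import permutations

    best_score, best = -np.inf, None
    for order in permutations(range(n)):
        total = 0.0
        assign = []
        for pos, v in enumerate(order):
            pred = order[:pos]
            cands = []
            for k in range(min(cap, len(pred)) + 1):
                for ps in combinations(sorted(pred), k):
                    cands.append((_family_score(rows, v, ps, score), ps))
            sc, ps = max(cands, key=lambda t: (t[0], -len(t[1])))
            total += sc
            assign.append((v, ps))
        if total > best_score:
            best_score = total
            best = assign
    parents: list[tuple[int, ...]] = [()] * n
    for v, ps in best:
        parents[v] = ps
    return best_score, parents


def structure_score(rows: np.ndarray, parents: Sequence[tuple[int, ...]], score: str = "bic") -> float:
    rows = np.asarray(rows, dtype=int)
    return sum(_family_score(rows, v, tuple(ps), score) for v, ps in enumerate(parents))


# ---------------------------------------------------------------------------
# CPTs and inference
# ---------------------------------------------------------------------------


@dataclass
class DiscreteBayesNet:
    """DAG over binary nodes with MLE (optionally smoothed) CPTs.

    ``cpts[v]`` has shape (2^|parents(v)|, 2); row i is the distribution of
    node v given the i-th parent configuration (parents read MSB-first in
    parent order).
    """

    parents: list[tuple[int, ...]]
    cpts: list[np.ndarray]

    def __post_init__(self) -> None:
        for v, table in enumerate(self.cpts):
            table = np.asarray(table, dtype=float)
            self.cpts[v] = table
            if table.shape != (2 ** len(self.parents[v]), 2):
                raise ContractError(f"CPT shape mismatch at node {v}")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
                raise ContractError(f"CPT rows must sum to 1 at node {v}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.parents)))
        for v, ps in enumerate(self.parents):
            g.add_edges_from((u, v) for u in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ContractError("parent sets must form a DAG")

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    def to_dict(self) -> dict:
        return {
            "parents": [list(p) for p in self.parents],
            "cpts": [c.tolist() for c in self.cpts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteBayesNet":
        return cls(
            [tuple(p) for p in d["parents"]],
            [np.asarray(c, dtype=float) for c in d["cpts"]],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DiscreteBayesNet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for v in range(self.n_nodes):
            lines.append(f"  n{v} [label=\"x[{v}]\"];")
        for v, ps in enumerate(self.parents):
            for u in ps:
                lines.append(f"  n{u} -> n{v};")
        return "\n".join(lines + ["}"])


def fit_cpts(
    parents: Sequence[tuple[int, ...]],
    rows: Sequence[Sequence[int]] | np.ndarray,
    alpha: float = 1.0,
) -> DiscreteBayesNet:
    """Maximum-likelihood CPTs with additive (Laplace) smoothing.

    ``alpha=1`` by default so unseen parent configurations get a uniform
    row instead of zeros that would break the argmax over classes.
    """
    rows = np.asarray(rows, dtype=int)
    cpts = []
    for v, ps in enumerate(parents):
        counts = _family_counts(rows, v, tuple(ps)) + alpha
        tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            table = np.where(tot > 0, counts / np.where(tot == 0, 1, tot), np.nan)
        if np.isnan(table).any():  # alpha=0 and unseen configuration
            table = np.nan_to_num(table, nan=0.5)
        cpts.append(table)
    return DiscreteBayesNet([tuple(p) for p in parents], cpts)


register_artifact("bayes_net")(DiscreteBayesNet)


def joint_probability(net: DiscreteBayesNet, evidence: Sequence[int]) -> float:
    """Product over nodes of P(node = e[node] | parents = e[parents])."""
    e = np.asarray(evidence, dtype=int)
    if e.shape != (net.n_nodes,):
        raise ContractError("evidence must assign every node")
    p = 1.0
    for v, ps in enumerate(net.parents):
        if ps:
            conf = int(sum(e[u] << (len(ps) - 1 - i) for i, u in enumerate(ps)))
        else:
            conf = 0
        p *= float(net.cpts[v][conf, e[v]])
    return p


def learn_bayes_net(
    rows: np.ndarray, score: str = "bic", max_parents: int = 3, alpha: float = 1.0
) -> DiscreteBayesNet:
    """Structure + CPTs in one call."""
    parents = learn_structure(rows, score=score, max_parents=max_parents)
    return fit_cpts(parents, rows, alpha=alpha)


def bn_classify(
    nets: dict[str, DiscreteBayesNet] | Sequence[tuple[str, DiscreteBayesNet]],
    evidence: Sequence[int],
) -> str:
    """Argmax over classes of the joint probability of the evidence.

    Ties go to the first class in order, with a warning.
    """
    items = list(nets.items()) if isinstance(nets, dict) else list(nets)
    sizes = {net.n_nodes for _, net in items}
    if len(sizes) > 1:
        raise ContractError("all class networks must share the node set")
    probs = [(cls, joint_probability(net, evidence)) for cls, net in items]
    best_p = max(p for _, p in probs)
    winners = [cls for cls, p in probs if p == best_p]
    if len(winners) > 1:
        warnings.warn(f"joint-probability tie among {winners}; keeping {winners[0]}", stacklevel=2)
    return winners[0]
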