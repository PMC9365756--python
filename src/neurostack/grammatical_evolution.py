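"""Grammatical evolution of combiner expressions.

A BNF grammar {N, T, P, S} maps integer genotypes onto expression trees:
at every non-terminal with k ordered alternatives the next codon c selects
alternative ``c mod k`` (leftmost derivation); exhausted genotypes wrap a
bounded number of times before the individual is declared invalid. The
engine also evolves derivation trees directly (position-independent grow
initialization, subtree crossover/mutation) under a bi-objective NSGA-II:
maximize F1 of the thresholded expression, minimize tree size.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from .evo_core import ContractError, ConvergenceTrace, crowding_distance, non_dominated_sort


class GrammarError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


# A symbol is ("NT", name) or ("T", literal-text).
Symbol = tuple[str, str]


@dataclass
class Grammar:
    """BNF tuple {N, T, P, S}: rules map each non-terminal to its ordered
    alternatives, each alternative a sequence of symbols."""

    rules: dict[str, list[list[Symbol]]]
    start: str

    def __post_init__(self) -> None:
        if self.start not in self.rules:
            raise GrammarError(f"start symbol <{self.start}> has no rule")
        for nt, alts in self.rules.items():
            for alt in alts:
                for kind, val in alt:
                    if kind == "NT" and val not in self.rules:
                        raise GrammarError(f"undefined non-terminal <{val}> referenced by <{nt}>")
        self._min_depth = self._compute_min_depths()

    # -- depth bookkeeping -------------------------------------------------
    def _compute_min_depths(self) -> dict[str, int]:
        """Minimum derivation-tree depth per non-terminal (leaf depth = 1).

        Computed by fixpoint; a non-terminal that never converges cannot
        derive a terminal-only string (dead end) and is rejected.
        """
        depth = {nt: math.inf for nt in self.rules}

        def alt_depth(alt: list[Symbol]) -> float:
            return 1 + max((depth[v] if k == "NT" else 1) for k, v in alt) if alt else 1

        changed = True
        while changed:
            changed = False
            for nt, alts in self.rules.items():
                d = min(alt_depth(a) for a in alts)
                if d < depth[nt]:
                    depth[nt] = d
                    changed = True
        dead = [nt for nt, d in depth.items() if math.isinf(d)]
        if dead:
            raise GrammarError(f"dead-end non-terminals (cannot terminate): {sorted(dead)}")
        self._growth = self._compute_growth_set()
        return {nt: int(d) for nt, d in depth.items()}

    def _compute_growth_set(self) -> set[str]:
        """Non-terminals from which derivation depth is unbounded: those
        that can reach a non-terminal that can reach itself."""
        reach: dict[str, set[str]] = {
            nt: {v for alt in alts for k, v in alt if k == "NT"} for nt, alts in self.rules.items()
        }
        changed = True
        while changed:
            changed = False
            for nt, rs in reach.items():
                new = rs | {w for v in rs for w in reach[v]}
                if new != rs:
                    reach[nt] = new
                    changed = True
        recursive = {nt for nt, rs in reach.items() if nt in rs}
        return {nt for nt, rs in reach.items() if nt in recursive or rs & recursive}

    def min_depth(self, nt: str) -> int:
        return self._min_depth[nt]

    def alt_min_depth(self, alt: list[Symbol]) -> int:
        """Depth the subtree rooted at the expanded node needs at minimum."""
        return 1 + max((self._min_depth[v] if k == "NT" else 1) for k, v in alt)

    def alt_is_recursive(self, alt: list[Symbol]) -> bool:
        """True when the alternative can grow unboundedly deep (references a
        non-terminal on a recursive cycle)."""
        return any(k == "NT" and v in self._growth for k, v in alt)

    @property
    def nonterminals(self) -> list[str]:
        return list(self.rules)

    @property
    def terminals(self) -> list[str]:
        out = []
        for alts in self.rules.values():
            for alt in alts:
                out += [v for k, v in alt if k == "T"]
        return sorted(set(out))

    # -- serialization -----------------------------------------------------
    def serialize(self) -> str:
        lines = []
        for nt in [self.start] + [n for n in self.rules if n != self.start]:
            alts = []
            for alt in self.rules[nt]:
                alts.append(" ".join(f"<{v}>" if k == "NT" else f'"{v}"' for k, v in alt))
            lines.append(f"<{nt}> ::= " + " | ".join(alts))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"text": self.serialize()}

    @classmethod
    def from_dict(cls, d: dict) -> "Grammar":
        return parse_bnf(d["text"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grammar):
            return NotImplemented
        return self.rules == other.rules and self.start == other.start


from .datamodel import register_artifact  # noqa: E402

register_artifact("grammar")(Grammar)

_NT_RE = re.compile(r"<([^<>\s]+)>")


def _parse_alternative(text: str) -> list[Symbol]:
    """Split one alternative into NT/terminal symbols.

    Terminals may be double-quoted (preserving spaces and '|') or bare runs
    of text between non-terminals.
    """
    symbols: list[Symbol] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "<":
            m = _NT_RE.match(text, i)
            if not m:
                raise GrammarError(f"malformed non-terminal near: {text[i:]!r}")
            symbols.append(("NT", m.group(1)))
            i = m.end()
        elif ch == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise GrammarError(f"unterminated quote in: {text!r}")
            symbols.append(("T", text[i + 1 : j]))
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < len(text) and text[j] not in '<"' and not text[j].isspace():
                j += 1
            symbols.append(("T", text[i:j]))
            i = j
    return symbols


def _split_alternatives(rhs: str) -> list[str]:
    """Split on '|' outside double quotes."""
    parts, buf, quoted = [], [], False
    for ch in rhs:
        if ch == '"':
            quoted = not quoted
            buf.append(ch)
        elif ch == "|" and not quoted:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def parse_bnf(text: str) -> Grammar:
    """Parse BNF: one rule per line, ``<nt> ::= alt | alt``; continuation
    lines starting with '|' extend the previous rule. Alternative order is
    preserved — it defines the codon semantics."""
    rules: dict[str, list[list[Symbol]]] = {}
    start: str | None = None
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "::=" in line:
            lhs, rhs = line.split("::=", 1)
            m = _NT_RE.fullmatch(lhs.strip())
            if not m:
                raise GrammarError(f"malformed rule head: {lhs.strip()!r}")
            current = m.group(1)
            if start is None:
                start = current
            if current in rules:
                raise GrammarError(f"duplicate rule for <{current}>")
            rules[current] = [_parse_alternative(a) for a in _split_alternatives(rhs)]
        elif line.startswith("|") and current is not None:
            rules[current] += [_parse_alternative(a) for a in _split_alternatives(line[1:])]
        else:
            raise GrammarError(f"unparseable grammar line: {raw!r}")
    if start is None:
        raise GrammarError("empty grammar")
    return Grammar(rules, start)


# ---------------------------------------------------------------------------
# Derivation trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    symbol: Symbol
    children: list["TreeNode"] = field(default_factory=list)

    def copy(self) -> "TreeNode":
        return TreeNode(self.symbol, [c.copy() for c in self.children])


@dataclass
class DerivationTree:
    """Root = start symbol, internal nodes = non-terminals, leaves =
    terminals; the phenotype is the left-to-right leaf concatenation."""

    root: TreeNode

    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            return 1 + max((d(c) for c in node.children), default=0)

        return d(self.root)

    @property
    def node_count(self) -> int:
        """Number of derivation (non-terminal) nodes — the tree-size
        objective counts expansion steps, not terminal leaves."""

        def n(node: TreeNode) -> int:
            me = 1 if node.symbol[0] == "NT" else 0
            return me + sum(n(c) for c in node.children)

        return n(self.root)

    @property
    def total_node_count(self) -> int:
        def n(node: TreeNode) -> int:
            return 1 + sum(n(c) for c in node.children)

        return n(self.root)

    @property
    def phenotype(self) -> str:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if not node.children:
                if node.symbol[0] == "T":
                    out.append(node.symbol[1])
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return "".join(out)

    def copy(self) -> "DerivationTree":
        return DerivationTree(self.root.copy())

    def internal_nodes(self) -> list[tuple[TreeNode, int]]:
        """(non-terminal node, its depth from root, root = 1)."""
        out: list[tuple[TreeNode, int]] = []

        def walk(node: TreeNode, d: int) -> None:
            if node.symbol[0] == "NT":
                out.append((node, d))
            for c in node.children:
                walk(c, d + 1)

        walk(self.root, 1)
        return out


# ---------------------------------------------------------------------------
# Genotype -> phenotype mapping (codon modulo rule)
# ---------------------------------------------------------------------------


def map_genotype(
    codons: Sequence[int],
    grammar: Grammar,
    max_depth: int = 15,
    max_wraps: int = 2,
) -> tuple[DerivationTree | None, int]:
    """Leftmost codon-modulo derivation.

    At a non-terminal with k > 1 alternatives the next codon c picks
    alternative ``c mod k`` (restricted to depth-feasible alternatives when
    at the budget); single-alternative non-terminals consume no codon.
    Returns (tree, wraps_used); tree is None when the genotype is invalid
    (codons exhausted beyond ``max_wraps`` or no feasible alternative).
    """
    codons = list(codons)
    if not codons:
        raise ContractError("codon array must be non-empty")
    pos = 0
    wraps = 0
    root = TreeNode(("NT", grammar.start))
    stack: list[tuple[TreeNode, int]] = [(root, 1)]  # leftmost on top
    while stack:
        node, depth = stack.pop()
        nt = node.symbol[1]
        alts = grammar.rules[nt]
        allowed = [a for a in alts if depth - 1 + grammar.alt_min_depth(a) <= max_depth]
        if not allowed:
            return None, wraps
        if len(allowed) > 1:
            if pos >= len(codons):
                wraps += 1
                if wraps > max_wraps:
                    return None, wraps
                pos = 0
            choice = allowed[codons[pos] % len(allowed)]
            pos += 1
        else:
            choice = allowed[0]
        node.children = [TreeNode(s) for s in choice]
        for child in reversed(node.children):
            if child.symbol[0] == "NT":
                stack.append((child, depth + 1))
    return DerivationTree(root), wraps


# ---------------------------------------------------------------------------
# Phenotype evaluation with protected operators
# ---------------------------------------------------------------------------


def _pdiv(a, b):
    """Protected division: 1.0 wherever |denominator| is (near) zero."""
    b_arr = np.asarray(b, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    safe = np.where(np.abs(b_arr) < 1e-9, 1.0, b_arr)
    out = np.where(np.abs(b_arr) < 1e-9, 1.0, a_arr / safe)
    return out if out.ndim else float(out)


def _plog(a):
    """Protected log: log(1 + |a|), finite everywhere."""
    out = np.log1p(np.abs(np.asarray(a, dtype=float)))
    return out if out.ndim else float(out)


def _pexp(a):
    """Protected exp: exponent clipped to +-50."""
    out = np.exp(np.clip(np.asarray(a, dtype=float), -50.0, 50.0))
    return out if out.ndim else float(out)


_EVAL_ENV = {
    "__builtins__": {},
    "tanh": np.tanh,
    "plog": _plog,
    "pexp": _pexp,
    "pdiv": _pdiv,
    "abs": np.abs,
}


class _Slots:
    """Indexable view over meta-feature columns; raises EvaluationError on
    an index outside the meta-feature vector."""

    def __init__(self, cols: list):
        self._cols = cols

    def __getitem__(self, i: int):
        try:
            return self._cols[i]
        except IndexError:
            raise EvaluationError(f"meta-feature index {i} out of range (have {len(self._cols)})") from None


def compile_phenotype(phenotype: str):
    """Compile a phenotype string into a callable over a slot vector/matrix."""
    try:
        code = compile(phenotype, "<phenotype>", "eval")
    except SyntaxError as exc:
        raise EvaluationError(f"unparseable phenotype {phenotype!r}: {exc}") from None

    def fn(cols: list):
        return eval(code, _EVAL_ENV, {"x": _Slots(cols)})

    return fn


def evaluate_phenotype(tree: DerivationTree | str, x: Sequence[float]) -> float:
    """Evaluate a combiner expression on one meta-feature vector."""
    pheno = tree.phenotype if isinstance(tree, DerivationTree) else tree
    val = compile_phenotype(pheno)([float(v) for v in x])
    return float(np.clip(val, -1e12, 1e12))


def evaluate_phenotype_matrix(tree: DerivationTree | str, X: np.ndarray) -> np.ndarray:
    """Vectorized evaluation over the rows of a meta-feature matrix."""
    pheno = tree.phenotype if isinstance(tree, DerivationTree) else tree
    X = np.asarray(X, dtype=float)
    cols = [X[:, j] for j in range(X.shape[1])]
    val = compile_phenotype(pheno)(cols)
    val = np.broadcast_to(np.asarray(val, dtype=float), (X.shape[0],)).copy()
    return np.clip(val, -1e12, 1e12)


# ---------------------------------------------------------------------------
# Tree initialization and variation
# ---------------------------------------------------------------------------


def grow_tree(
    grammar: Grammar,
    rng: np.random.Generator,
    max_depth: int,
    start: str | None = None,
) -> DerivationTree:
    """Plain grow: expand depth-feasible alternatives uniformly at random."""
    root = TreeNode(("NT", start or grammar.start))
    stack = [(root, 1)]
    while stack:
        node, depth = stack.pop()
        alts = grammar.rules[node.symbol[1]]
        allowed = [a for a in alts if depth - 1 + grammar.alt_min_depth(a) <= max_depth]
        if not allowed:  # unreachable when max_depth >= min_depth(start)
            allowed = [min(alts, key=grammar.alt_min_depth)]
        choice = allowed[rng.integers(0, len(allowed))]
        node.children = [TreeNode(s) for s in choice]
        for child in reversed(node.children):
            if child.symbol[0] == "NT":
                stack.append((child, depth + 1))
    return DerivationTree(root)


def pi_grow(grammar: Grammar, rng: np.random.Generator, max_depth: int) -> DerivationTree:
    """Position-independent grow.

    Open non-terminals are expanded in random order; while no branch has
    reached ``max_depth`` the deepest open node is forced to pick a
    recursive (depth-increasing) alternative when one fits, so trees reach
    but never exceed the depth budget.
    """
    root = TreeNode(("NT", grammar.start))
    open_nodes: list[tuple[TreeNode, int]] = [(root, 1)]
    reached = False
    while open_nodes:
        growth_depths = [d for nd, d in open_nodes if nd.symbol[1] in grammar._growth]
        deepest = max(growth_depths) if growth_depths else None
        i = int(rng.integers(0, len(open_nodes)))
        node, depth = open_nodes.pop(i)
        alts = grammar.rules[node.symbol[1]]
        allowed = [a for a in alts if depth - 1 + grammar.alt_min_depth(a) <= max_depth]
        if not allowed:
            allowed = [min(alts, key=grammar.alt_min_depth)]
        if not reached and deepest is not None and depth == deepest and node.symbol[1] in grammar._growth:
            recursive = [a for a in allowed if grammar.alt_is_recursive(a)]
            if recursive:
                allowed = recursive
            else:
                reached = True  # budget cannot be pushed further
        choice = allowed[rng.integers(0, len(allowed))]
        node.children = [TreeNode(s) for s in choice]
        if depth + 1 >= max_depth:
            reached = True
        for child in node.children:
            if child.symbol[0] == "NT":
                open_nodes.append((child, depth + 1))
    return DerivationTree(root)


def subtree_crossover(
    a: DerivationTree,
    b: DerivationTree,
    rng: np.random.Generator,
    max_depth: int = 15,
    max_retries: int = 10,
) -> tuple[DerivationTree, DerivationTree]:
    """Swap subtrees rooted at a random pair of same-label non-terminals.

    Children that would exceed ``max_depth`` are rejected and resampled;
    after ``max_retries`` failures copies of the parents are returned.
    """
    labels_a = {n.symbol[1] for n, _ in a.internal_nodes()}
    labels_b = {n.symbol[1] for n, _ in b.internal_nodes()}
    common = sorted(labels_a & labels_b)
    if not common:
        return a.copy(), b.copy()
    for _ in range(max_retries):
        ca, cb = a.copy(), b.copy()
        label = common[rng.integers(0, len(common))]
        nodes_a = [(n, d) for n, d in ca.internal_nodes() if n.symbol[1] == label]
        nodes_b = [(n, d) for n, d in cb.internal_nodes() if n.symbol[1] == label]
        na, da = nodes_a[rng.integers(0, len(nodes_a))]
        nb, db = nodes_b[rng.integers(0, len(nodes_b))]
        na.children, nb.children = nb.children, na.children
        if ca.depth <= max_depth and cb.depth <= max_depth:
            return ca, cb
    return a.copy(), b.copy()


def subtree_mutation(
    t: DerivationTree,
    grammar: Grammar,
    rng: np.random.Generator,
    events: int = 1,
    max_depth: int = 15,
) -> DerivationTree:
    """Regrow the subtree under ``events`` randomly chosen non-terminals."""
    out = t.copy()
    for _ in range(events):
        nodes = out.internal_nodes()
        node, depth = nodes[rng.integers(0, len(nodes))]
        budget = max(max_depth - depth + 1, grammar.min_depth(node.symbol[1]))
        repl = grow_tree(grammar, rng, budget, start=node.symbol[1])
        node.children = repl.root.children
    return out


# ---------------------------------------------------------------------------
# Default combiner grammar
# ---------------------------------------------------------------------------


def default_combiner_grammar(n_slots: int, demographic_slots: int = 0) -> Grammar:
    """Arithmetic combiner grammar over meta-feature slots x[0..K-1].

    When demographic slots are enabled the index rule is extended with the
    extra positions (e.g. gender and age appended after the task outputs),
    so the expressions may mix classifier outputs with demographics.
    """
    if n_slots < 1:
        raise GrammarError("need at least one meta-feature slot")
    idx = " | ".join(str(i) for i in range(n_slots + demographic_slots))
    text = f"""
<expr> ::= (<expr> <op> <expr>) | <pre>(<expr>) | <var> | <const>
<op> ::= + | - | *
<pre> ::= tanh | plog | pexp
<var> ::= x[<idx>]
<idx> ::= {idx}
<const> ::= 0.1 | 0.5 | 1.0 | 2.0
"""
    return parse_bnf(text)


# ---------------------------------------------------------------------------
# Bi-objective evolution of combiner trees
# ---------------------------------------------------------------------------


@dataclass
class GEConfig:
    """NSGA-II settings for combiner evolution (defaults follow common GE
    practice for this problem: pop 300 / 1500 generations, subtree
    operators, PI-grow initialization, depth cap 15)."""

    population_size: int = 300
    elite_size: int = 30
    generations: int = 1500
    p_crossover: float = 0.9
    mutation_events: int = 1
    selection_proportion: float = 0.5
    max_init_depth: int = 10
    max_depth: int = 15
    initialization: str = "pi_grow"
    threshold: float = 0.5
    max_wraps: int = 2

    def __post_init__(self) -> None:
        if self.elite_size >= self.population_size:
            raise ContractError("elite_size must be < population_size")
        if self.max_init_depth > self.max_depth:
            raise ContractError("max_init_depth must be <= max_depth")


@dataclass
class GEIndividual:
    tree: DerivationTree
    fitness: tuple[float, float] | None = None  # (f1, -node_count), maximized


def _ge_evaluate(tree: DerivationTree, X: np.ndarray, y: np.ndarray, threshold: float,
                 cache: dict[str, float]) -> tuple[float, float]:
    pheno = tree.phenotype
    if pheno not in cache:
        try:
            vals = evaluate_phenotype_matrix(pheno, X)
            pred = (vals >= threshold).astype(int)
            cache[pheno] = float(f1_score(y, pred, zero_division=0))
        except EvaluationError:
            cache[pheno] = 0.0
    return cache[pheno], -float(tree.node_count)


def evolve_combiner(
    X: np.ndarray,
    y: np.ndarray,
    grammar: Grammar,
    cfg: GEConfig | None = None,
    seed: int = 0,
) -> tuple[DerivationTree, list[tuple[tuple[float, float], DerivationTree]], ConvergenceTrace]:
    """Evolve a combiner expression: maximize F1, minimize tree size.

    Returns (best tree, final non-dominated front as ((f1, node_count),
    tree) pairs, convergence trace). Best = highest F1, then fewest nodes.
    """
    cfg = cfg or GEConfig()
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ContractError("combiner target must contain both classes")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    cache: dict[str, float] = {}

    def make_tree() -> DerivationTree:
        # ramp target depths across the initial population for diversity
        depth = int(rng.integers(grammar.min_depth(grammar.start), cfg.max_init_depth + 1))
        if cfg.initialization == "pi_grow":
            return pi_grow(grammar, rng, depth)
        return grow_tree(grammar, rng, depth)

    pop = [GEIndividual(make_tree()) for _ in range(cfg.population_size)]
    for ind in pop:
        ind.fitness = _ge_evaluate(ind.tree, X, y, cfg.threshold, cache)
    trace = ConvergenceTrace()
    trace.record(0, [i.fitness for i in pop])

    n_parents = max(2, int(round(cfg.selection_proportion * cfg.population_size)))
    for gen in range(1, cfg.generations + 1):
        fronts = non_dominated_sort([i.fitness for i in pop])
        rank = {i: r for r, fr in enumerate(fronts) for i in fr}
        cd: dict[int, float] = {}
        for fr in fronts:
            d = crowding_distance([pop[i].fitness for i in fr])
            cd.update({i: d[j] for j, i in enumerate(fr)})

        def pick() -> GEIndividual:
            if len(pop) == 1:
                return pop[0]
            i, j = rng.choice(len(pop), size=2, replace=False)
            if rank[i] != rank[j]:
                return pop[i if rank[i] < rank[j] else j]
            return pop[i if cd[i] >= cd[j] else j]

        parents = [pick() for _ in range(n_parents)]
        offspring: list[GEIndividual] = []
        k = 0
        while len(offspring) < cfg.population_size:
            a = parents[k % n_parents]
            b = parents[(k + 1) % n_parents]
            k += 2
            if rng.random() < cfg.p_crossover:
                t1, t2 = subtree_crossover(a.tree, b.tree, rng, cfg.max_depth)
            else:
                t1, t2 = a.tree.copy(), b.tree.copy()
            # mutation applies to the population resulting from the crossover
            t1 = subtree_mutation(t1, grammar, rng, cfg.mutation_events, cfg.max_depth)
            t2 = subtree_mutation(t2, grammar, rng, cfg.mutation_events, cfg.max_depth)
            offspring += [GEIndividual(t1), GEIndividual(t2)]
        offspring = offspring[: cfg.population_size]
        for ind in offspring:
            ind.fitness = _ge_evaluate(ind.tree, X, y, cfg.threshold, cache)

        pool = pop + offspring
        pool_fronts = non_dominated_sort([i.fitness for i in pool])
        nxt: list[GEIndividual] = []
        for fr in pool_fronts:
            if len(nxt) + len(fr) <= cfg.population_size:
                nxt += [pool[i] for i in fr]
            else:
                d = crowding_distance([pool[i].fitness for i in fr])
                order = sorted(range(len(fr)), key=lambda j: d[j], reverse=True)
                nxt += [pool[fr[j]] for j in order[: cfg.population_size - len(nxt)]]
                break
        pop = nxt
        trace.record(gen, [i.fitness for i in pop])

    front_idx = non_dominated_sort([i.fitness for i in pop])[0]
    seen: set[tuple] = set()
    front: list[tuple[tuple[float, float], DerivationTree]] = []
    for i in front_idx:
        f1, negn = pop[i].fitness
        tag = (f1, negn, pop[i].tree.phenotype)
        if tag in seen:
            continue
        seen.add(tag)
        front.append(((f1, -negn), pop[i].tree))
    # best: highest F1, then fewest nodes, then lexicographic phenotype
    best = max(front, key=lambda p: (p[0][0], -p[0][1], p[1].phenotype))[1]
    return best, front, trace
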