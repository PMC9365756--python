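import numpy as np
import pytest

from neurostack.evo_core import ContractError
from neurostack.grammatical_evolution import (
    DerivationTree,
    GEConfig,
    GrammarError,
    default_combiner_grammar,
    evaluate_phenotype,
    evaluate_phenotype_matrix,
    evolve_combiner,
    grow_tree,
    map_genotype,
    parse_bnf,
    pi_grow,
    subtree_crossover,
    subtree_mutation,
)

TOY = """
<e> ::= (<e> <op> <e>) | x | y
<op> ::= + | *
"""


class TestParseBnf:
    def test_alternative_order_preserved(self):
        g = parse_bnf("<e> ::= a | b")
        assert g.start == "e"
        assert [alt[0][1] for alt in g.rules["e"]] == ["a", "b"]

    def test_undefined_nonterminal_named(self):
        with pytest.raises(GrammarError, match="<x>"):
            parse_bnf("<e> ::= <x> | a")

    def test_dead_end_detected(self):
        with pytest.raises(GrammarError, match="loop"):
            parse_bnf("<e> ::= <loop>\n<loop> ::= <loop> a")

    def test_serialize_roundtrip(self):
        g = parse_bnf(TOY)
        assert parse_bnf(g.serialize()) == g

    def test_continuation_lines(self):
        g = parse_bnf("<e> ::= a\n  | b\n  | c")
        assert len(g.rules["e"]) == 3

    def test_shipped_grammar_file_matches_builtin(self):
        from pathlib import Path

        path = Path(__file__).parent.parent / "grammars" / "combiner_default.bnf"
        g = parse_bnf(path.read_text())
        assert g == default_combiner_grammar(3)


class TestMapping:
    def test_codon_modulo_picks_alternative(self):
        g = parse_bnf("<e> ::= x | y")
        tree, wraps = map_genotype([7], g)
        assert tree.phenotype == "y" and wraps == 0

    def test_single_alternative_consumes_no_codon(self):
        g = parse_bnf("<e> ::= x")
        tree, _ = map_genotype([99, 99], g)
        assert tree.phenotype == "x"

    def test_exhaustion_without_wraps_is_invalid(self):
        tree, _ = map_genotype([0, 0], parse_bnf(TOY), max_wraps=0)
        assert tree is None  # two codons cannot finish the recursive branch

    def test_wrap_reuses_codons(self):
        # pass 1: e->rec (0), left e->x (1); wrap: op->+ (0 mod 2), right e->x (1)
        g = parse_bnf(TOY)
        tree, wraps = map_genotype([0, 1], g, max_wraps=1)
        assert tree is not None and wraps == 1
        assert tree.phenotype == "(x+x)"

    def test_hand_derived_phenotypes(self):
        """Oracle: enact the modulo rule by hand on the 2-rule toy grammar."""
        g = parse_bnf(TOY)
        cases = {
            (1,): "x",
            (2,): "y",
            (4,): "x",          # 4 mod 3 = 1
            (0, 1, 0, 2): "(x+y)",
            (0, 2, 1, 1): "(y*x)",
            (0, 0, 1, 0, 2, 1, 2): "((x+y)*y)",  # nested leftmost derivation
        }
        for codons, pheno in cases.items():
            tree, _ = map_genotype(list(codons), g, max_wraps=0)
            assert tree is not None and tree.phenotype == pheno

    def test_depth_limit_never_violated(self):
        g = parse_bnf(TOY)
        rng = np.random.default_rng(0)
        for _ in range(500):
            codons = rng.integers(0, 1000, size=rng.integers(1, 30)).tolist()
            tree, _ = map_genotype(codons, g, max_depth=8, max_wraps=2)
            if tree is not None:
                assert tree.depth <= 8

    def test_mapping_deterministic(self):
        g = default_combiner_grammar(3)
        rng = np.random.default_rng(1)
        codons = rng.integers(0, 256, size=20).tolist()
        t1, _ = map_genotype(codons, g)
        t2, _ = map_genotype(codons, g)
        assert (t1 is None) == (t2 is None)
        if t1 is not None:
            assert t1.phenotype == t2.phenotype

    def test_empty_codons_rejected(self):
        with pytest.raises(ContractError):
            map_genotype([], parse_bnf(TOY))


class TestEvaluate:
    def test_identity_slot(self):
        assert evaluate_phenotype("x[0]", (0.7, 0.2)) == pytest.approx(0.7)

    def test_sum(self):
        assert evaluate_phenotype("(x[0] + x[1])", (0.7, 0.2)) == pytest.approx(0.9)

    def test_protected_division_fallback(self):
        assert evaluate_phenotype("pdiv(x[0], x[1])", (0.3, 0.0)) == pytest.approx(1.0)

    def test_protected_exp_log_finite(self):
        assert np.isfinite(evaluate_phenotype("pexp(pexp(x[0]))", (100.0,)))
        assert np.isfinite(evaluate_phenotype("plog(x[0])", (0.0,)))

    def test_index_out_of_range(self):
        from neurostack.grammatical_evolution import EvaluationError

        with pytest.raises(EvaluationError):
            evaluate_phenotype("x[5]", (0.1, 0.2))

    def test_matrix_matches_scalar(self):
        X = np.array([[0.1, 0.9], [0.4, 0.2], [0.8, 0.5]])
        pheno = "tanh((x[0] * x[1]))"
        vec = evaluate_phenotype_matrix(pheno, X)
        for i in range(3):
            assert vec[i] == pytest.approx(evaluate_phenotype(pheno, X[i]))


class TestTreeOps:
    def _tree(self, seed=0, depth=8):
        return pi_grow(default_combiner_grammar(3), np.random.default_rng(seed), depth)

    def test_pi_grow_respects_and_reaches_depth(self):
        g = default_combiner_grammar(3)
        depths = []
        for s in range(60):
            t = pi_grow(g, np.random.default_rng(s), 8)
            assert t.depth <= 8
            depths.append(t.depth)
        # forcing recursive choices drives trees to (near) the budget
        assert max(depths) == 8 and np.mean(depths) > 5

    def test_phenotype_is_evaluable(self):
        X = np.random.default_rng(0).random((5, 3))
        for s in range(20):
            t = self._tree(seed=s)
            assert np.isfinite(evaluate_phenotype_matrix(t, X)).all()

    def test_crossover_identical_parents(self):
        t = self._tree(seed=1)
        c1, c2 = subtree_crossover(t, t, np.random.default_rng(0))
        assert c1.phenotype == t.phenotype and c2.phenotype == t.phenotype

    def test_crossover_depth_respected(self):
        g = default_combiner_grammar(3)
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = pi_grow(g, rng, 10)
            b = pi_grow(g, rng, 10)
            c1, c2 = subtree_crossover(a, b, rng, max_depth=15)
            assert c1.depth <= 15 and c2.depth <= 15

    def test_mutation_zero_events_identity(self):
        t = self._tree(seed=3)
        g = default_combiner_grammar(3)
        out = subtree_mutation(t, g, np.random.default_rng(0), events=0)
        assert out.phenotype == t.phenotype

    def test_mutation_depth_respected(self):
        g = default_combiner_grammar(3)
        rng = np.random.default_rng(4)
        for _ in range(100):
            t = pi_grow(g, rng, 10)
            m = subtree_mutation(t, g, rng, events=1, max_depth=15)
            assert m.depth <= 15

    def test_node_count_counts_expansions(self):
        g = default_combiner_grammar(2)
        tree, _ = map_genotype([2, 0], g)  # <expr> -> <var> -> x[<idx> -> 0]
        assert tree.phenotype == "x[0]"
        assert tree.node_count == 3  # expr, var, idx


class TestEvolveCombiner:
    def _planted(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x0 = np.where(y == 1, rng.uniform(0.7, 1.0, n), rng.uniform(0.0, 0.3, n))
        X = np.column_stack([x0, rng.random(n), rng.random(n)])
        return X, y

    def test_zero_generations_front_from_initial_population(self):
        X, y = self._planted()
        g = default_combiner_grammar(3)
        cfg = GEConfig(population_size=20, elite_size=2, generations=0)
        _, front, _ = evolve_combiner(X, y, g, cfg, seed=0)
        assert len(front) >= 1

    def test_same_seed_identical_fronts(self):
        X, y = self._planted()
        g = default_combiner_grammar(3)
        cfg = GEConfig(population_size=20, elite_size=2, generations=5)
        _, f1, _ = evolve_combiner(X, y, g, cfg, seed=7)
        _, f2, _ = evolve_combiner(X, y, g, cfg, seed=7)
        assert [(o, t.phenotype) for o, t in f1] == [(o, t.phenotype) for o, t in f2]

    def test_single_class_target_rejected(self):
        X, _ = self._planted()
        with pytest.raises(ContractError):
            evolve_combiner(X, np.ones(len(X), dtype=int), default_combiner_grammar(3))

    def test_front_is_nondominated(self):
        from neurostack.evo_core import dominates

        X, y = self._planted(seed=2)
        cfg = GEConfig(population_size=30, elite_size=3, generations=10)
        _, front, _ = evolve_combiner(X, y, default_combiner_grammar(3), cfg, seed=1)
        objs = [(f1, -n) for (f1, n), _ in front]
        for a in objs:
            assert not any(dominates(b, a) for b in objs if b != a)
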