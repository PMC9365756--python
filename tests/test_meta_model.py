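import numpy as np
import pandas as pd
import pytest

from neurostack.classifiers import ClassifierSpec
from neurostack.datamodel import ConfigurationError
from neurostack.evo_core import ContractError
from neurostack.grammatical_evolution import GEConfig, parse_bnf
from neurostack.meta_model import (
    BinaryTask,
    MetaModel,
    MetaModelConfig,
    balance,
    build_tasks,
    generate_meta_features,
    train_meta_model,
    validate,
)
from neurostack.synthetic_data import simulate_meta_features, simulate_pairwise_separable

KNN = ClassifierSpec("knn", {"n_neighbors": 3})


@pytest.fixture(scope="module")
def pairwise_data():
    X, y, subsets = simulate_pairwise_separable({"A": 25, "B": 20, "C": 20}, seed=5)
    return X, y, subsets


class TestBuildTasks:
    def test_three_classes_three_pairwise_tasks(self):
        subsets = {"AvsB": ["f0"], "AvsC": ["f1"], "BvsC": ["f2"]}
        tasks = build_tasks(["A", "B", "C"], subsets)
        assert [t.name for t in tasks] == ["AvsB", "AvsC", "BvsC"]

    def test_two_classes_single_task(self):
        tasks = build_tasks(["A", "B"], {"AvsB": ["f0"]})
        assert len(tasks) == 1

    def test_four_classes_six_tasks(self):
        subsets = {f"{a}vs{b}": ["f0"] for a, b in
                   [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]}
        assert len(build_tasks(list("ABCD"), subsets)) == 6

    def test_missing_subset_rejected(self):
        with pytest.raises(ConfigurationError, match="BvsC"):
            build_tasks(["A", "B", "C"], {"AvsB": ["f0"], "AvsC": ["f1"]})

    def test_one_vs_rest_scheme(self):
        subsets = {f"{c}vsRest": ["f0"] for c in "ABC"}
        tasks = build_tasks(["A", "B", "C"], subsets, scheme="one_vs_rest")
        assert all(t.negative_class == "__rest__" for t in tasks)


class TestGenerateMetaFeatures:
    def test_row_bookkeeping(self, pairwise_data):
        X, y, subsets = pairwise_data
        tasks = build_tasks(["A", "B", "C"], subsets, KNN)
        meta = generate_meta_features(X, y, tasks, inner_iterations=3, inner_folds=5, seed=0)
        assert meta.X.shape == (len(y) * 3, 3)
        assert set(meta.provenance[:, 1]) == {0, 1, 2}

    def test_single_iteration_each_sample_once(self, pairwise_data):
        X, y, subsets = pairwise_data
        tasks = build_tasks(["A", "B", "C"], subsets, KNN)
        meta = generate_meta_features(X, y, tasks, inner_iterations=1, inner_folds=5, seed=0)
        assert sorted(meta.sample_index.tolist()) == list(range(len(y)))

    def test_separable_task_scores_polarized(self, pairwise_data):
        X, y, subsets = pairwise_data
        tasks = build_tasks(["A", "B", "C"], subsets, KNN)
        meta = generate_meta_features(X, y, tasks, inner_iterations=1, inner_folds=5, seed=0)
        j = meta.task_names.index("AvsB")
        assert meta.X[meta.y == "A", j].mean() > 0.8
        assert meta.X[meta.y == "B", j].mean() < 0.2

    def test_small_class_stratification_error(self, pairwise_data):
        X, y, subsets = pairwise_data
        tasks = build_tasks(["A", "B", "C"], subsets, KNN)
        tiny = np.array(["A"] * 20 + ["B"] * 3 + ["C"] * 20)
        with pytest.raises(ContractError):
            generate_meta_features(X.iloc[:43], tiny, tasks, inner_folds=5)


class TestBalance:
    def test_counts_equalized_to_minority(self):
        meta = simulate_meta_features({"A": 100, "B": 60, "C": 40}, 3, seed=0)
        out = balance(meta, seed=1)
        _, counts = np.unique(out.y, return_counts=True)
        assert counts.tolist() == [40, 40, 40]

    def test_already_balanced_identity_multiset(self):
        meta = simulate_meta_features({"A": 30, "B": 30}, 2, seed=0)
        out = balance(meta, seed=0)
        assert sorted(out.sample_index.tolist()) == sorted(meta.sample_index.tolist())

    def test_seed_controls_selection(self):
        meta = simulate_meta_features({"A": 50, "B": 20}, 2, seed=0)
        o1 = balance(meta, seed=1)
        o2 = balance(meta, seed=2)
        _, c1 = np.unique(o1.y, return_counts=True)
        _, c2 = np.unique(o2.y, return_counts=True)
        assert c1.tolist() == c2.tolist() == [20, 20]
        assert balance(meta, seed=1).sample_index.tolist() == o1.sample_index.tolist()


class TestPredict:
    def test_argmax_and_tie_rules(self):
        # hand-built model with identity combiners over fixed meta values
        tasks = build_tasks(["A", "B", "C"],
                            {"AvsB": ["f0"], "AvsC": ["f0"], "BvsC": ["f0"]}, KNN)
        model = MetaModel(["A", "B", "C"], tasks, mode="reference_ovr")
        model.combiners = {"A": ([0], None), "B": ([1], None), "C": ([2], None)}
        pred = model.predict_meta(np.array([[0.2, 0.9, 0.1]]))
        assert pred[0] == "B"
        with pytest.warns(UserWarning, match="tie"):
            pred = model.predict_meta(np.array([[0.5, 0.5, 0.5]]))
        assert pred[0] == "A"

    def test_missing_feature_named(self, pairwise_data):
        X, y, subsets = pairwise_data
        cfg = MetaModelConfig(mode="reference_ovr", classifier=KNN,
                              inner_iterations=1, seed=0)
        ovr = {f"{c}vsRest": list(X.columns[:2]) for c in "ABC"}
        model = train_meta_model(X, y, ovr, cfg)
        with pytest.raises(ContractError, match="AB_a"):
            model.predict(X.drop(columns=["AB_a"]))

    def test_single_task_identity_combiner_reduces_to_binary_classifier(self):
        """With one pairwise task and the identity combiner, the meta-model
        is exactly the underlying binary classifier."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f0": np.concatenate([rng.normal(2, 1, 25), rng.normal(-2, 1, 25)]),
                          "f1": rng.normal(size=50)})
        y = np.array(["A"] * 25 + ["B"] * 25)
        tasks = build_tasks(["A", "B"], {"AvsB": ["f0"]}, KNN)
        for t in tasks:
            t.fit(X, y, seed=0)
        model = MetaModel(["A", "B"], tasks, mode="reference_ovr")
        # class A sees the task score s, class B sees 1 - s
        model.combiners = {"A": ([0], None), "B": ([0], lambda sub: 1 - sub[:, 0])}
        meta = model.task_outputs(X)
        pred = model.predict_meta(meta)
        direct = np.where(tasks[0].score(X) >= 0.5, "A", "B")
        assert (pred == direct).all()


class TestDemographics:
    def test_demographic_slots_appended_and_scaled(self, pairwise_data):
        X, y, subsets = pairwise_data
        X = X.copy()
        rng = np.random.default_rng(0)
        X["age"] = rng.uniform(55, 85, len(y))
        cfg = MetaModelConfig(mode="bn", classifier=KNN, inner_iterations=1,
                              demographics=["age"], seed=0)
        model = train_meta_model(X, y, subsets, cfg)
        assert model.n_slots == 4  # 3 tasks + age
        meta = model.task_outputs(X)
        assert meta.shape[1] == 4
        assert (meta[:, 3] >= 0).all() and (meta[:, 3] <= 1).all()
        # every combiner sees the demographic slot
        for slots, _ in model.combiners.values():
            assert 3 in slots

    def test_ge_mode_with_demographics_trains(self, pairwise_data):
        X, y, subsets = pairwise_data
        X = X.copy()
        X["age"] = np.linspace(55, 85, len(y))
        cfg = MetaModelConfig(
            mode="ge", classifier=KNN, inner_iterations=1,
            demographics=["age"],
            ge=GEConfig(population_size=15, elite_size=2, generations=3), seed=0,
        )
        model = train_meta_model(X, y, subsets, cfg)
        pred = model.predict(X)
        assert set(pred) <= {"A", "B", "C"}


def test_compare_strategies_runs_all_modes(pairwise_data):
    from neurostack.meta_model import compare_strategies

    X, y, subsets = pairwise_data
    ovr = {f"{c}vsRest": sorted({f for t, fs in subsets.items() for f in fs if c in t})
           for c in "ABC"}
    cfg = MetaModelConfig(classifier=KNN, inner_iterations=1,
                          ge=GEConfig(population_size=12, elite_size=2, generations=2),
                          seed=0)
    results = compare_strategies(X, y, subsets, ovr, cfg)
    assert set(results) == {"ge", "bn", "reference_ovr"}
    for reports in results.values():
        assert len(reports) == 5


class TestValidate:
    def test_five_fold_reports_and_stratification(self, pairwise_data):
        X, y, subsets = pairwise_data
        cfg = MetaModelConfig(mode="bn", classifier=KNN, inner_iterations=2, seed=0)
        reports = validate(X, y, subsets, cfg)
        assert len(reports) == 5
        overall = {c: (y == c).mean() for c in "ABC"}
        for r in reports:
            yt = y[r.test_index]
            for c in "ABC":
                assert abs((yt == c).sum() - overall[c] * len(yt)) <= 1

    def test_no_test_sample_in_training(self, pairwise_data):
        X, y, subsets = pairwise_data
        cfg = MetaModelConfig(mode="bn", classifier=KNN, inner_iterations=2, seed=0)
        for r in validate(X, y, subsets, cfg):
            assert set(r.train_index).isdisjoint(r.test_index)
            assert len(set(r.train_index) | set(r.test_index)) == len(y)

    def test_ge_mode_end_to_end_small(self, pairwise_data):
        X, y, subsets = pairwise_data
        cfg = MetaModelConfig(
            mode="ge", classifier=KNN, inner_iterations=2,
            ge=GEConfig(population_size=20, elite_size=2, generations=8), seed=0,
        )
        reports = validate(X, y, subsets, cfg)
        mean_f1 = np.mean([r.metrics.f1 for r in reports])
        assert mean_f1 > 0.6  # pairwise-separable data: combiners must work

    def test_bn_deterministic_meta_rows_train_exactly(self):
        meta = simulate_meta_features({"A": 30, "B": 30, "C": 30}, 3,
                                      deterministic=True, seed=0)
        from neurostack.bayes_network import learn_bayes_net, joint_probability, binarize

        nets = {}
        for c in ["A", "B", "C"]:
            rows = np.vstack([binarize(r) for r in meta.X[meta.y == c]])
            nets[c] = learn_bayes_net(rows, max_parents=1)
        correct = 0
        for i in range(len(meta.y)):
            e = binarize(meta.X[i])
            probs = {c: joint_probability(nets[c], e) for c in nets}
            correct += max(probs, key=probs.get) == meta.y[i]
        assert correct == len(meta.y)
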