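"""Two-layer stacking meta-model.

Layer 1: one binary classifier per unordered class pair (one-vs-one), each
trained on its own feature subset and only on examples of its two classes.
Layer 2: per-class combiners — grammatical-evolution expressions or
discrete Bayesian networks — over the layer-1 output vector x; a sample is
assigned the class whose combiner yields the highest value.

Meta-features for combiner training are produced by repeated inner
cross-validation so no sample's meta-feature row ever comes from a
classifier that saw it in training; the outer validation loop holds out a
fold end-to-end. Every meta-feature row carries a provenance tag
(outer_fold, inner_iteration) so leakage freedom is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .bayes_network import DiscreteBayesNet, binarize, joint_probability, learn_bayes_net
from .classifiers import ClassifierSpec, MetricsReport, compute_metrics, make_classifier
from .datamodel import ConfigurationError, Dataset
from .evo_core import ContractError
from .grammatical_evolution import (
    DerivationTree,
    GEConfig,
    default_combiner_grammar,
    evaluate_phenotype_matrix,
    evolve_combiner,
)


@dataclass
class BinaryTask:
    """A pairwise (or one-vs-rest) classification problem."""

    name: str
    positive_class: str
    negative_class: str  # "__rest__" for one-vs-rest tasks
    feature_subset: list[str]
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("svm_rbf"))
    model: object | None = None

    def __post_init__(self) -> None:
        if self.positive_class == self.negative_class:
            raise ConfigurationError("positive and negative class must differ")
        if not self.feature_subset:
            raise ConfigurationError(f"task {self.name}: empty feature subset")

    def involves(self, cls: str) -> bool:
        return cls in (self.positive_class, self.negative_class)

    def rows_mask(self, y: np.ndarray) -> np.ndarray:
        if self.negative_class == "__rest__":
            return np.ones(len(y), dtype=bool)
        return (y == self.positive_class) | (y == self.negative_class)

    def binary_target(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) == self.positive_class).astype(int)

    def fit(self, X: pd.DataFrame, y: np.ndarray, seed: int) -> "BinaryTask":
        mask = self.rows_mask(y)
        spec = ClassifierSpec(self.classifier.family, self.classifier.hyperparameters, seed)
        model = make_classifier(spec)
        model.fit(X.loc[mask, self.feature_subset].to_numpy(dtype=float), self.binary_target(y[mask]))
        self.model = model
        return self

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """P(positive class) in [0,1] for every row (also rows outside the pair)."""
        if self.model is None:
            raise ContractError(f"task {self.name} is not fitted")
        M = X[self.feature_subset].to_numpy(dtype=float)
        if hasattr(self.model, "predict_proba"):
            proba = self.model.predict_proba(M)
            pos_col = list(self.model.classes_).index(1)
            return proba[:, pos_col]
        # logistic squash of the decision margin: per-sample and monotone
        d = self.model.decision_function(M)
        return 1.0 / (1.0 + np.exp(-d))


def build_tasks(
    classes: Sequence[str],
    feature_subsets: Mapping[str, Sequence[str]],
    classifier: ClassifierSpec | None = None,
    scheme: str = "pairwise",
) -> list[BinaryTask]:
    """One task per unordered class pair (canonical class order), or per
    class for the one-vs-rest reference model. ``feature_subsets`` is keyed
    by task name (``"AvsB"`` / ``"AvsRest"``)."""
    classifier = classifier or ClassifierSpec("svm_rbf")
    tasks = []
    if scheme == "pairwise":
        for a, b in combinations(classes, 2):
            name = f"{a}vs{b}"
            if name not in feature_subsets:
                raise ConfigurationError(f"no feature subset for task {name!r}")
            tasks.append(BinaryTask(name, a, b, list(feature_subsets[name]), classifier))
    elif scheme == "one_vs_rest":
        for a in classes:
            name = f"{a}vsRest"
            if name not in feature_subsets:
                raise ConfigurationError(f"no feature subset for task {name!r}")
            tasks.append(BinaryTask(name, a, "__rest__", list(feature_subsets[name]), classifier))
    else:
        raise ConfigurationError(f"unknown task scheme {scheme!r}")
    return tasks


@dataclass
class MetaFeatureTable:
    """Layer-1 outputs per sample: one column per task (+ optional
    demographics), the original class as target, and provenance tags."""

    X: np.ndarray  # (rows, n_slots), values in [0,1] for task slots
    y: np.ndarray  # class tokens
    task_names: list[str]
    provenance: np.ndarray  # (rows, 2): outer_fold, inner_iteration
    sample_index: np.ndarray  # original row id of each meta row

    @property
    def n_slots(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "MetaFeatureTable":
        return MetaFeatureTable(
            self.X[mask], self.y[mask], list(self.task_names), self.provenance[mask], self.sample_index[mask]
        )


def generate_meta_features(
    X: pd.DataFrame,
    y: np.ndarray,
    tasks: list[BinaryTask],
    inner_iterations: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    outer_fold: int = -1,
) -> MetaFeatureTable:
    """Out-of-fold layer-1 outputs, stacked over repeated inner CV.

    For every inner iteration a fresh stratified K-fold split is drawn; a
    task's classifiers are fitted on the training side (restricted to the
    task's two classes) and applied to every held-out sample — including
    samples outside the pair, which still receive that task's score. Each
    iteration contributes one meta row per sample.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < inner_folds:
        raise ContractError(
            f"smallest class ({counts.min()}) cannot be stratified into {inner_folds} folds"
        )
    n = len(y)
    blocks = []
    for it in range(inner_iterations):
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + it)
        meta = np.zeros((n, len(tasks)))
        for tr, te in skf.split(np.zeros(n), y):
            for j, task in enumerate(tasks):
                fitted = BinaryTask(
                    task.name, task.positive_class, task.negative_class,
                    task.feature_subset, task.classifier,
                ).fit(X.iloc[tr], y[tr], seed=seed + it)
                meta[te, j] = fitted.score(X.iloc[te])
        prov = np.column_stack([np.full(n, outer_fold), np.full(n, it)])
        blocks.append((meta, prov))
    Xm = np.vstack([b[0] for b in blocks])
    prov = np.vstack([b[1] for b in blocks])
    ym = np.tile(y, inner_iterations)
    idx = np.tile(np.arange(n), inner_iterations)
    return MetaFeatureTable(Xm, ym, [t.name for t in tasks], prov, idx)


def balance(meta: MetaFeatureTable, seed: int = 0) -> MetaFeatureTable:
    """Randomly drop rows from majority classes until all counts equal the
    minority count. No synthetic rows are created."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(meta.y, return_counts=True)
    m = counts.min()
    keep = np.zeros(len(meta.y), dtype=bool)
    for c in classes:
        idx = np.flatnonzero(meta.y == c)
        keep[rng.choice(idx, size=m, replace=False)] = True
    return meta.subset(keep)


# ---------------------------------------------------------------------------
# Combiners and the assembled model
# ---------------------------------------------------------------------------


@dataclass
class MetaModelConfig:
    mode: str = "ge"  # ge | bn | reference_ovr
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("svm_rbf"))
    inner_iterations: int = 10
    inner_folds: int = 5
    outer_folds: int = 5
    combiner_scope: str = "class_tasks"  # or "all_tasks"; bn always uses all
    #: feature columns appended (min-max scaled to [0,1]) as extra x slots
    #: after the task outputs, e.g. a gender indicator and age. Off by
    #: default: demographics in the combiner can bias the diagnosis.
    demographics: list[str] = field(default_factory=list)
    ge: GEConfig = field(default_factory=GEConfig)
    bn_score: str = "bic"
    bn_max_parents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ge", "bn", "reference_ovr"):
            raise ConfigurationError(f"unknown meta-model mode {self.mode!r}")


@dataclass
class MetaModel:
    classes: list[str]
    tasks: list[BinaryTask]
    mode: str
    # per class: (slot indices into the meta vector, combiner object)
    combiners: dict[str, tuple[list[int], object]] = field(default_factory=dict)
    # demographic slots appended after the task outputs: name -> (lo, hi)
    demo_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_slots(self) -> int:
        return len(self.tasks) + len(self.demo_bounds)

    def _slots_for(self, cls: str, scope: str) -> list[int]:
        demo = list(range(len(self.tasks), self.n_slots))
        if scope == "all_tasks" or self.mode == "bn":
            return list(range(len(self.tasks))) + demo
        return [i for i, t in enumerate(self.tasks) if t.involves(cls)] + demo

    def demographic_slots(self, X: pd.DataFrame) -> np.ndarray | None:
        if not self.demo_bounds:
            return None
        cols = []
        for name, (lo, hi) in self.demo_bounds.items():
            v = X[name].to_numpy(dtype=float)
            cols.append(np.clip((v - lo) / (hi - lo), 0, 1) if hi > lo else np.full(len(v), 0.5))
        return np.column_stack(cols)

    def task_outputs(self, X: pd.DataFrame) -> np.ndarray:
        out = np.column_stack([t.score(X) for t in self.tasks])
        demo = self.demographic_slots(X)
        return out if demo is None else np.hstack([out, demo])

    def combiner_values(self, meta_X: np.ndarray) -> np.ndarray:
        """(rows, classes) matrix of combiner outputs."""
        vals = np.zeros((len(meta_X), len(self.classes)))
        for j, cls in enumerate(self.classes):
            slots, comb = self.combiners[cls]
            sub = meta_X[:, slots]
            if isinstance(comb, DerivationTree):
                vals[:, j] = evaluate_phenotype_matrix(comb, sub)
            elif isinstance(comb, DiscreteBayesNet):
                for i in range(len(sub)):
                    vals[i, j] = joint_probability(comb, binarize(sub[i]))
            elif callable(comb):  # user-supplied combiner over the slot matrix
                vals[:, j] = np.asarray(comb(sub), dtype=float)
            else:  # identity / reference: mean of the class's task outputs
                vals[:, j] = sub.mean(axis=1)
        return vals

    def predict_meta(self, meta_X: np.ndarray) -> np.ndarray:
        vals = self.combiner_values(meta_X)
        ties = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            warnings.warn(f"{int(ties.sum())} combiner ties; resolved by class order", stacklevel=2)
        return np.asarray(self.classes, dtype=object)[vals.argmax(axis=1)]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = {f for t in self.tasks for f in t.feature_subset} - set(X.columns)
        if missing:
            raise ContractError(f"sample is missing features: {sorted(missing)}")
        return self.predict_meta(self.task_outputs(X))


def train_combiners(
    meta: MetaFeatureTable,
    model: MetaModel,
    cfg: MetaModelConfig,
) -> None:
    """Fit one combiner per class on the (balanced) meta table.

    GE mode: 50/50 class-stratified split of the meta rows; evolution runs
    on the training half, the held-out half is where the reported F1 of the
    evolved expression comes from. BN mode: the meta rows of class c,
    binarized, train class c's network.
    """
    for cls in model.classes:
        slots = model._slots_for(cls, cfg.combiner_scope)
        sub = meta.X[:, slots]
        target = (meta.y == cls).astype(int)
        if cfg.mode == "ge":
            if len(np.unique(target)) < 2:
                raise ContractError(f"combiner target for {cls!r} is single-class")
            idx_tr, _ = train_test_split(
                np.arange(len(target)),
                test_size=0.5,
                stratify=target,
                random_state=cfg.seed,
            )
            grammar = default_combiner_grammar(len(slots))
            best, _, _ = evolve_combiner(
                sub[idx_tr], target[idx_tr], grammar, cfg.ge, seed=cfg.seed
            )
            model.combiners[cls] = (slots, best)
        elif cfg.mode == "bn":
            rows = np.vstack([binarize(r) for r in sub[meta.y == cls]])
            net = learn_bayes_net(rows, score=cfg.bn_score, max_parents=cfg.bn_max_parents)
            model.combiners[cls] = (slots, net)
        else:  # reference: identity combiner over the class's tasks
            model.combiners[cls] = (slots, None)


def train_meta_model(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_subsets: Mapping[str, Sequence[str]],
    cfg: MetaModelConfig | None = None,
    classes: Sequence[str] | None = None,
    outer_fold: int = -1,
) -> MetaModel:
    """Full training on one dataset: layer-1 tasks on all rows, combiners on
    out-of-fold meta-features (balanced to the minority class first)."""
    cfg = cfg or MetaModelConfig()
    y = np.asarray(y)
    classes = list(classes) if classes is not None else list(dict.fromkeys(y))
    scheme = "one_vs_rest" if cfg.mode == "reference_ovr" else "pairwise"
    tasks = build_tasks(classes, feature_subsets, cfg.classifier, scheme)
    model = MetaModel(classes, tasks, cfg.mode)
    for name in cfg.demographics:
        v = X[name].to_numpy(dtype=float)
        model.demo_bounds[name] = (float(v.min()), float(v.max()))

    meta = generate_meta_features(
        X, y, tasks, cfg.inner_iterations, cfg.inner_folds, seed=cfg.seed, outer_fold=outer_fold
    )
    demo = model.demographic_slots(X)
    if demo is not None:
        meta = MetaFeatureTable(
            np.hstack([meta.X, demo[meta.sample_index]]),
            meta.y,
            meta.task_names + list(model.demo_bounds),
            meta.provenance,
            meta.sample_index,
        )
    _, counts = np.unique(meta.y, return_counts=True)
    if len(set(counts)) > 1:
        meta = balance(meta, seed=cfg.seed)
    train_combiners(meta, model, cfg)
    for t in tasks:
        t.fit(X, y, seed=cfg.seed)
    return model


@dataclass
class FoldReport:
    fold: int
    metrics: MetricsReport
    train_index: np.ndarray
    test_index: np.ndarray


def validate(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_subsets: Mapping[str, Sequence[str]],
    cfg: MetaModelConfig | None = None,
) -> list[FoldReport]:
    """Outer stratified K-fold validation of the full pipeline.

    Each fold is held out end-to-end: meta-feature generation, balancing
    and combiner training see only the other folds. Returns one report per
    fold with the train/test row sets for leakage auditing.
    """
    cfg = cfg or MetaModelConfig()
    y = np.asarray(y)
    classes = list(dict.fromkeys(y))
    skf = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = train_meta_model(
            X.iloc[tr], y[tr], feature_subsets, cfg, classes=classes, outer_fold=fold
        )
        pred = model.predict(X.iloc[te])
        rep = compute_metrics(y[te], pred, classes=classes)
        reports.append(FoldReport(fold, rep, tr, te))
    return reports


def compare_strategies(
    X: pd.DataFrame,
    y: np.ndarray,
    pairwise_subsets: Mapping[str, Sequence[str]],
    ovr_subsets: Mapping[str, Sequence[str]],
    cfg: MetaModelConfig | None = None,
) -> dict[str, list[FoldReport]]:
    """Validate the GE and Bayesian-network combiners and the one-vs-rest
    reference model under the same outer CV, for side-by-side comparison."""
    from dataclasses import replace

    cfg = cfg or MetaModelConfig()
    out: dict[str, list[FoldReport]] = {}
    for mode, subsets in (
        ("ge", pairwise_subsets),
        ("bn", pairwise_subsets),
        ("reference_ovr", ovr_subsets),
    ):
        out[mode] = validate(X, np.asarray(y), subsets, replace(cfg, mode=mode))
    return out
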