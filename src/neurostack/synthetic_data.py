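"""Synthetic clinical-style fixtures with known ground truth.

Emulates the shape of a dementia-diagnosis feature table: three diagnostic
classes with the 171/72/87 imbalance of a typical memory-clinic cohort,
demographic variables (age, gender), numeric cognitive-test scores, and
nonnegative per-brain-region hypometabolic voxel counts (47-region Brodmann
or 90-region AAL layout). Region counts are zero-inflated Poisson —
controls are near-all-zero so qualitative binarization is meaningful —
and informative features carry class-dependent mean shifts or
hypometabolism probabilities declared in the ground truth. MCAR missingness
is applied at a configurable rate. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import Dataset, ValidationError
from .meta_model import MetaFeatureTable

ATLAS_SIZES = {"brodmann47": 47, "aal90": 90}


@dataclass
class SimSpec:
    """Generative settings; defaults mirror the emulated cohort shape."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 171, "bvFTD": 72, "HC": 87}
    )
    n_cognitive: int = 10
    atlas: str = "brodmann47"
    #: numeric informative features: name -> per-class mean shift in
    #: within-class SD units (cognitive columns are named cog_0, cog_1, ...)
    numeric_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: region-count informative features: name -> per-class
    #: (hypometabolism probability, Poisson intensity); regions are bm_1..bm_K
    region_effects: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    #: background hypometabolism probability / intensity for diseased classes
    background_hypo: tuple[float, float] = (0.05, 2.0)
    control_class: str = "HC"
    control_hypo: tuple[float, float] = (0.01, 1.0)
    missing_rate: float = 0.0
    include_demographics: bool = True
    nominal_vars: Mapping[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atlas not in ATLAS_SIZES:
            raise ValidationError(f"atlas must be one of {sorted(ATLAS_SIZES)}")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.control_class not in self.n_per_class:
            raise ValidationError("control_class must be a class")


@dataclass
class GroundTruth:
    informative: list[str]
    numeric_effects: dict
    region_effects: dict
    missing_mask: pd.DataFrame | None = None


def default_effects(spec: SimSpec, n_informative: int = 5, effect: float = 2.0):
    """Plant `n_informative` class-separating effects: cognitive shifts and
    class-specific hypometabolic regions."""
    classes = list(spec.n_per_class)
    diseased = [c for c in classes if c != spec.control_class]
    num: dict[str, dict[str, float]] = {}
    reg: dict[str, dict[str, tuple[float, float]]] = {}
    for i in range(n_informative):
        if i % 2 == 0 and i // 2 < spec.n_cognitive:
            name = f"cog_{i // 2}"
            num[name] = {c: -effect * (1 + (j % 2) * 0.5) for j, c in enumerate(diseased)}
        else:
            name = f"bm_{i + 1}"
            reg[name] = {diseased[i % len(diseased)]: (0.9, 15.0)}
    return num, reg


def simulate(spec: SimSpec) -> tuple[Dataset, GroundTruth]:
    """Draw a labelled feature table + ground truth from the spec."""
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.n_per_class)
    labels = np.concatenate([[c] * n for c, n in spec.n_per_class.items()])
    n = len(labels)
    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}

    if spec.include_demographics:
        age_mean = {c: (68.0 if c != spec.control_class else 64.0) for c in classes}
        cols["age"] = np.concatenate(
            [rng.normal(age_mean[c], 8.0, spec.n_per_class[c]) for c in classes]
        )
        kinds["age"] = "numeric"
        cols["gender"] = np.array(
            ["F" if v else "M" for v in rng.random(n) < 0.5], dtype=object
        )
        kinds["gender"] = "nominal"
    for name, levels in spec.nominal_vars.items():
        cols[name] = rng.choice(levels, size=n)
        kinds[name] = "nominal"

    for j in range(spec.n_cognitive):
        name = f"cog_{j}"
        shifts = spec.numeric_effects.get(name, {})
        vals = np.concatenate(
            [rng.normal(shifts.get(c, 0.0), 1.0, spec.n_per_class[c]) for c in classes]
        )
        cols[name] = vals
        kinds[name] = "numeric"

    for r in range(1, ATLAS_SIZES[spec.atlas] + 1):
        name = f"bm_{r}"
        eff = spec.region_effects.get(name, {})
        parts = []
        for c in classes:
            cn = spec.n_per_class[c]
            if c in eff:
                p, lam = eff[c]
            elif c == spec.control_class:
                p, lam = spec.control_hypo
            else:
                p, lam = spec.background_hypo
            hypo = rng.random(cn) < p
            counts = np.where(hypo, 1 + rng.poisson(lam, cn), 0)
            parts.append(counts)
        cols[name] = np.concatenate(parts).astype(float)
        kinds[name] = "region_count"

    X = pd.DataFrame(cols)
    mask = None
    if spec.missing_rate > 0:
        mask = pd.DataFrame(
            rng.random(X.shape) < spec.missing_rate, index=X.index, columns=X.columns
        )
        X = X.mask(mask)
    data = Dataset(X, kinds, pd.Series(labels), classes)
    informative = sorted(set(spec.numeric_effects) | set(spec.region_effects))
    truth = GroundTruth(informative, dict(spec.numeric_effects), dict(spec.region_effects), mask)
    return data, truth


def simulate_pairwise_separable(
    n_per_class: Mapping[str, int],
    effect: float = 2.5,
    n_noise: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, list[str]]]:
    """Three-class data where each class pair separates on its own disjoint
    feature pair (plus pure-noise columns).

    For pair (p, q) two dedicated features put p at +effect and q at
    -effect (third class at 0), so every pairwise task is easy on its own
    subset while no single feature block separates one class from the rest.
    Returns (X, y, pairwise feature subsets keyed "PvsQ").
    """
    from itertools import combinations

    rng = np.random.default_rng(seed)
    classes = list(n_per_class)
    y = np.concatenate([[c] * n_per_class[c] for c in classes])
    cols: dict[str, np.ndarray] = {}
    subsets: dict[str, list[str]] = {}
    for p, q in combinations(classes, 2):
        names = [f"{p}{q}_a", f"{p}{q}_b"]
        subsets[f"{p}vs{q}"] = names
        for name in names:
            mean = {p: effect, q: -effect}
            cols[name] = np.concatenate(
                [rng.normal(mean.get(c, 0.0), 1.0, n_per_class[c]) for c in classes]
            )
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.normal(0.0, 1.0, len(y))
    return pd.DataFrame(cols), y, subsets


def simulate_meta_features(
    n_per_class: Mapping[str, int],
    k_tasks: int,
    signal_map: Mapping[str, Mapping[int, tuple[float, float]]] | None = None,
    deterministic: bool = False,
    seed: int = 0,
) -> MetaFeatureTable:
    """Direct meta-feature fixtures in [0,1]^k.

    ``signal_map[class][slot] = (a, b)`` gives the Beta distribution of that
    slot for that class (default Beta(1,1), uninformative). In
    ``deterministic`` mode slot j is exactly 1 for class j and 0 elsewhere,
    so any sane combiner separates the classes perfectly.
    """
    rng = np.random.default_rng(seed)
    classes = list(n_per_class)
    rows, ys = [], []
    for ci, c in enumerate(classes):
        cn = n_per_class[c]
        block = np.zeros((cn, k_tasks))
        for j in range(k_tasks):
            if deterministic:
                block[:, j] = 1.0 if (ci % k_tasks) == j else 0.0
            else:
                a, b = (signal_map or {}).get(c, {}).get(j, (1.0, 1.0))
                block[:, j] = rng.beta(a, b, cn)
        rows.append(block)
        ys += [c] * cn
    X = np.vstack(rows)
    y = np.asarray(ys, dtype=object)
    prov = np.column_stack([np.full(len(y), -1), np.zeros(len(y))])
    return MetaFeatureTable(X, y, [f"task_{j}" for j in range(k_tasks)], prov, np.arange(len(y)))
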