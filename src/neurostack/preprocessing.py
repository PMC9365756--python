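"""Cleaning, iterative-forest imputation, encoding and binarization.

Imputation follows the MissForest scheme: initial mean/mode fill, then
variables are revisited in ascending order of missing count, each one
re-imputed by a forest of randomized trees trained on the currently
completed table, until the normalized change in the imputed values first
increases or drops below a tolerance. Observed cells are never modified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, ExtraTreesRegressor

from .datamodel import ConfigurationError, Dataset, ValidationError


class UnimputableError(ValueError):
    """A column contains no observed values to learn from."""


@dataclass
class ImputationConfig:
    """Settings for the iterative forest imputer.

    Defaults mirror common clinical practice with this imputer: mean/mode
    initial fill, 50 random-split trees per forest, squared-error split
    criterion, early stopping at 1e-3, at most 100 sweeps.
    """

    max_iterations: int = 100
    tolerance: float = 1e-3
    n_trees: int = 50

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


@dataclass
class CleaningReport:
    dropped_columns: list[tuple[str, str]] = field(default_factory=list)
    flagged_rows: list[tuple[int, str]] = field(default_factory=list)


def _default_consistency_rule(data: Dataset, control_class: str) -> list[int]:
    """Rows whose region counts are all zero yet are labelled as diseased."""
    region_cols = data.columns_of_kind("region_count")
    if not region_cols:
        return []
    counts = data.X[region_cols].apply(pd.to_numeric, errors="coerce")
    all_zero = (counts.fillna(0) == 0).all(axis=1) & counts.notna().any(axis=1)
    diseased = data.y != control_class
    return [int(i) for i in data.X.index[(all_zero & diseased).to_numpy()]]


def clean(
    data: Dataset,
    drop_list: Sequence[str] = (),
    consistency_rule: Callable[[Dataset], list[int]] | None = None,
    control_class: str | None = None,
) -> tuple[Dataset, CleaningReport]:
    """Drop listed columns and flag (never silently delete) suspect rows.

    The default consistency rule flags rows with an entirely normal brain
    metabolism (all region counts zero) that carry a disease label; the
    caller decides what to do with them.
    """
    report = CleaningReport()
    unknown = [c for c in drop_list if c not in data.feature_names]
    if unknown:
        raise ConfigurationError(f"drop_list names unknown columns: {unknown}")
    X = data.X.drop(columns=list(drop_list))
    kinds = {c: k for c, k in data.kinds.items() if c not in drop_list}
    for c in drop_list:
        report.dropped_columns.append((c, "listed for removal"))
    out = Dataset(X, kinds, data.y.copy(), list(data.class_names))

    if consistency_rule is not None:
        flagged = consistency_rule(out)
        reason = "violates consistency rule"
    else:
        ctrl = control_class if control_class is not None else data.class_names[-1]
        flagged = _default_consistency_rule(out, ctrl)
        reason = "all region counts zero but labelled as diseased"
    for i in flagged:
        report.flagged_rows.append((i, reason))
    return out, report


# ---------------------------------------------------------------------------
# Iterative forest imputation
# ---------------------------------------------------------------------------


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def _predictor_matrix(work: pd.DataFrame, kinds: dict[str, str], exclude: str) -> np.ndarray:
    """Numeric predictor matrix from all columns but `exclude` (nominals one-hot)."""
    cols = [c for c in work.columns if c != exclude]
    parts = []
    for c in cols:
        if kinds[c] == "nominal":
            parts.append(pd.get_dummies(work[c], prefix=c).to_numpy(dtype=float))
        else:
            parts.append(work[c].to_numpy(dtype=float)[:, None])
    if not parts:
        return np.zeros((len(work), 1))
    return np.hstack(parts)


def impute(data: Dataset, cfg: ImputationConfig | None = None, seed: int = 0) -> Dataset:
    """Fill every missing cell by iterative random-split-forest prediction.

    Deterministic given ``(data, cfg, seed)``. Region-count imputations are
    rounded half-away-from-zero and clipped at 0.
    """
    cfg = cfg or ImputationConfig()
    mask = data.missing_mask()
    if not mask.to_numpy().any():
        return data.copy()

    for c in data.feature_names:
        if mask[c].all():
            raise UnimputableError(f"column {c!r} is fully missing")

    kinds = data.kinds
    work = data.X.copy()
    # (1) initial fill: mean for numeric-like, mode for nominal
    for c in data.feature_names:
        if not mask[c].any():
            continue
        if kinds[c] == "nominal":
            fill = work[c].mode(dropna=True).iloc[0]
        else:
            fill = pd.to_numeric(work[c], errors="coerce").mean()
        work[c] = work[c].fillna(fill)

    # (2) visiting order: ascending missing count, ties by column order
    with_missing = [c for c in data.feature_names if mask[c].any()]
    order = sorted(with_missing, key=lambda c: (int(mask[c].sum()), data.feature_names.index(c)))

    num_cols = [c for c in order if kinds[c] != "nominal"]
    cat_cols = [c for c in order if kinds[c] == "nominal"]

    rng = np.random.default_rng(seed)
    prev_stat = np.inf
    snapshot = work.copy()
    for _ in range(cfg.max_iterations):
        before = work.copy()
        for c in order:
            miss = mask[c].to_numpy()
            obs = ~miss
            Xmat = _predictor_matrix(work, kinds, c)
            rs = int(rng.integers(0, 2**31 - 1))
            if kinds[c] == "nominal":
                model = ExtraTreesClassifier(
                    n_estimators=cfg.n_trees, random_state=rs, n_jobs=1
                )
                model.fit(Xmat[obs], work.loc[obs, c])
                pred = model.predict(Xmat[miss])
            else:
                model = ExtraTreesRegressor(
                    n_estimators=cfg.n_trees,
                    criterion="squared_error",
                    random_state=rs,
                    n_jobs=1,
                )
                model.fit(Xmat[obs], work.loc[obs, c].to_numpy(dtype=float))
                pred = model.predict(Xmat[miss])
            work.loc[miss, c] = pred

        # (4) stopping statistic: normalized squared change over imputed
        # numeric cells + fraction of changed nominal imputations
        stat = 0.0
        if num_cols:
            new = np.concatenate([work.loc[mask[c], c].to_numpy(dtype=float) for c in num_cols])
            old = np.concatenate([before.loc[mask[c], c].to_numpy(dtype=float) for c in num_cols])
            denom = float(np.sum(new**2))
            stat += float(np.sum((new - old) ** 2)) / denom if denom > 0 else 0.0
        if cat_cols:
            changed = sum((work.loc[mask[c], c] != before.loc[mask[c], c]).sum() for c in cat_cols)
            total = sum(int(mask[c].sum()) for c in cat_cols)
            stat += changed / total
        if stat >= prev_stat:
            work = snapshot  # change grew: keep the previous sweep's values
            break
        snapshot = work.copy()
        if stat < cfg.tolerance:
            break
        prev_stat = stat

    # integer-kind columns: round half-away-from-zero, clip at 0
    for c in data.columns_of_kind("region_count"):
        if mask[c].any():
            vals = work[c].to_numpy(dtype=float)
            vals[mask[c].to_numpy()] = np.clip(
                _round_half_away(vals[mask[c].to_numpy()]), 0, None
            )
            work[c] = vals

    # observed cells are restored verbatim (forests never touch them, but be safe)
    work = work.where(mask, data.X)
    return Dataset(work, dict(kinds), data.y.copy(), list(data.class_names))


def one_hot_encode(data: Dataset) -> tuple[Dataset, dict[str, list[str]]]:
    """Replace each nominal column with one binary column per observed level.

    No level is dropped: with n distinct values the column becomes n binary
    indicators named ``<col>=<value>``, exactly one of which is 1 per row.
    """
    mapping: dict[str, list[str]] = {}
    cols: list[pd.Series] = []
    kinds: dict[str, str] = {}
    for c in data.feature_names:
        if data.kinds[c] != "nominal":
            cols.append(data.X[c])
            kinds[c] = data.kinds[c]
            continue
        if data.X[c].isna().any():
            raise ValidationError(f"nominal column {c!r} has missing values; impute first")
        levels = sorted(data.X[c].unique())
        if len(levels) == 1:
            warnings.warn(f"nominal column {c!r} has a single level", stacklevel=2)
        derived = []
        for lv in levels:
            name = f"{c}={lv}"
            cols.append((data.X[c] == lv).astype(float).rename(name))
            kinds[name] = "numeric"
            derived.append(name)
        mapping[c] = derived
    X = pd.concat(cols, axis=1)
    return Dataset(X, kinds, data.y.copy(), list(data.class_names)), mapping


def binarize_hypometabolism(data: Dataset, threshold_voxels: int = 1) -> Dataset:
    """Qualitative hypometabolism: region count v -> 1 if v >= threshold else 0.

    A region is called hypometabolic when its hypometabolic-voxel count
    reaches the threshold (default 1 voxel); the threshold is a clinical
    choice left to the user. Idempotent for any threshold >= 1.
    """
    if threshold_voxels < 1:
        raise ConfigurationError("threshold_voxels must be >= 1")
    out = data.copy()
    for c in data.columns_of_kind("region_count"):
        col = out.X[c].to_numpy(dtype=float)
        miss = np.isnan(col)
        col = (col >= threshold_voxels).astype(float)
        col[miss] = np.nan
        out.X[c] = col
    return out
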