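"""Core data containers and flat-file I/O.

A :class:`Dataset` couples a feature table with per-column variable kinds
(``numeric``, ``nominal``, ``region_count``) and a class label per row.
Missing values use a single internal sentinel (``numpy.nan``); the CSV reader
maps a configurable set of input spellings (``""`` and ``"NA"`` by default)
onto it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_KINDS = ("numeric", "nominal", "region_count")

#: default input spellings interpreted as a missing value
DEFAULT_MISSING_TOKENS = ("", "NA")


class FormatError(ValueError):
    """Malformed input file (duplicate columns, missing header...)."""


class ConfigurationError(ValueError):
    """Inconsistent user configuration."""


class ValidationError(ValueError):
    """Data violates a declared column kind or invariant."""


@dataclass
class FeatureSpace:
    """The universe of candidate features a genotype indexes into."""

    names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        if not self.names:
            raise ValidationError("feature space must be non-empty")

    @property
    def num_features(self) -> int:
        return len(self.names)


@dataclass
class Dataset:
    """Feature table + per-column kinds + class labels.

    ``X`` holds one column per feature in file order; missing cells are NaN
    (nominal columns are object dtype and may hold NaN alongside string
    tokens). ``kinds`` maps every column to one of :data:`VALID_KINDS`.
    """

    X: pd.DataFrame
    kinds: dict[str, str]
    y: pd.Series
    class_names: list[str]

    def __post_init__(self) -> None:
        if list(self.X.columns) != list(self.kinds.keys()):
            # allow kinds given in any order but covering exactly the columns
            if set(self.X.columns) != set(self.kinds):
                raise ValidationError("feature_kinds must cover exactly the feature columns")
            self.kinds = {c: self.kinds[c] for c in self.X.columns}
        for c, k in self.kinds.items():
            if k not in VALID_KINDS:
                raise ConfigurationError(f"unknown kind {k!r} for column {c!r}")
        if len(self.y) != len(self.X):
            raise ValidationError("labels must align with rows")
        if not self.class_names:
            raise ValidationError("class_names must be non-empty")
        unknown = set(self.y.dropna()) - set(self.class_names)
        if unknown:
            raise ValidationError(f"labels outside class_names: {sorted(unknown)}")
        self._check_region_counts()

    def _check_region_counts(self) -> None:
        for c, k in self.kinds.items():
            if k != "region_count":
                continue
            col = pd.to_numeric(self.X[c], errors="coerce")
            obs = col[self.X[c].notna()]
            bad = obs.isna() | (obs < 0) | (obs != np.floor(obs))
            if bad.any():
                row = int(bad[bad].index[0])
                raise ValidationError(
                    f"region_count column {c!r} has a non-(nonnegative-integer) "
                    f"value at row {row}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def missing_mask(self) -> pd.DataFrame:
        return self.X.isna()

    def feature_space(self) -> FeatureSpace:
        return FeatureSpace(self.feature_names)

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c, k in self.kinds.items() if k == kind]

    def numeric_matrix(self) -> np.ndarray:
        """All-numeric view; raises if a nominal column is still present."""
        nominal = self.columns_of_kind("nominal")
        if nominal:
            raise ValidationError(f"nominal columns not yet encoded: {nominal}")
        return self.X.to_numpy(dtype=float)

    def copy(self) -> "Dataset":
        return Dataset(self.X.copy(), dict(self.kinds), self.y.copy(), list(self.class_names))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.X.equals(other.X)
            and self.kinds == other.kinds
            and self.y.equals(other.y)
            and self.class_names == other.class_names
        )


@dataclass
class RunConfig:
    """Provenance-bearing run configuration, echoed in every result file."""

    seed: int = 0
    cv_folds: int = 5
    cv_repeats: int = 1
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cv_folds < 1 or self.cv_repeats < 1:
            raise ConfigurationError("cv_folds and cv_repeats must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def read_dataset(
    path: str | Path,
    label_column: str,
    kind_map: Mapping[str, str],
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    class_names: Sequence[str] | None = None,
) -> Dataset:
    """Read a header-bearing CSV into a :class:`Dataset`.

    Column order follows the file minus the label column. Cells matching
    ``missing_tokens`` become the missing sentinel. Class order defaults to
    first appearance in the file.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header:
        raise FormatError("empty file: header row required")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"duplicate feature names in header: {dupes}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in raw.columns:
        raise FormatError(f"label column {label_column!r} not in header")
    feats = [c for c in raw.columns if c != label_column]
    unknown = [c for c in feats if c not in kind_map]
    if unknown:
        raise ConfigurationError(f"no kind declared for columns: {unknown}")

    X = raw[feats].replace(list(missing_tokens), np.nan)
    kinds = {c: kind_map[c] for c in feats}
    for c in feats:
        if kinds[c] in ("numeric", "region_count"):
            try:
                X[c] = pd.to_numeric(X[c])
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"non-numeric value in column {c!r}: {exc}") from None
    y = raw[label_column].replace(list(missing_tokens), np.nan)
    if y.isna().any():
        raise ValidationError("missing class labels are not supported")
    if class_names is None:
        class_names = list(dict.fromkeys(y))
    return Dataset(X, kinds, y, list(class_names))


def write_dataset(data: Dataset, path: str | Path, label_column: str = "label") -> None:
    out = data.X.copy()
    out[label_column] = data.y.values
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result-artifact serialization: a small registry of (to_dict, from_dict)
# pairs keyed by a "__type__" tag so write/read round-trips arbitrary
# artifacts (fronts, metric reports, grammars, nets).
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Any] = {}


def register_artifact(name: str):
    def deco(cls):
        _REGISTRY[name] = cls
        cls.__artifact_name__ = name
        return cls

    return deco


def _encode(obj: Any) -> Any:
    if hasattr(obj, "__artifact_name__") and hasattr(obj, "to_dict"):
        return {"__type__": obj.__artifact_name__, **_encode(obj.to_dict())}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__type__" in obj:
            cls = _REGISTRY[obj["__type__"]]
            payload = {k: _decode(v) for k, v in obj.items() if k != "__type__"}
            return cls.from_dict(payload)
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_results(obj: Any, path: str | Path, config: RunConfig | None = None) -> None:
    """Serialize a result artifact (with the run config for provenance)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    doc = {"config": config.to_dict() if config else None, "artifact": _encode(obj)}
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_results(path: str | Path) -> Any:
    doc = json.loads(Path(path).read_text())
    return _decode(doc["artifact"])
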