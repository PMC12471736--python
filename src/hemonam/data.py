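"""Cohort tables, ratio derivation, stratified splitting and z-score standardization.

The exchange object throughout the package is :class:`FeatureTable`: an
``n x p`` float matrix with named columns, a binary label vector and optional
subject identifiers.  All preprocessing is leakage-safe by construction: the
standardizer is fitted on training rows only and then applied everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The four ratio columns of the panel and the columns they are derived from.
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "NEU/LY": ("NEU", "LY"),
    "PLT/LY": ("PLT", "LY"),
    "MPV/LY": ("MPV", "LY"),
    "LY/MO": ("LY", "MO"),
}


class SchemaError(ValueError):
    """Raised when a cohort file or table violates the expected schema."""


@dataclass
class FeatureTable:
    """Numeric cohort: feature matrix, feature names, binary labels.

    Parameters
    ----------
    values : (n, p) float array
    feature_names : sequence of p unique names
    labels : (n,) array of 0/1
    subject_ids : optional sequence of n identifiers
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D matrix")
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise SchemaError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.values.shape[0],):
            raise SchemaError("labels must be one per row")
        if not np.isin(self.labels, [0, 1]).all():
            raise SchemaError("labels must be 0 or 1")
        self.labels = self.labels.astype(int)
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise SchemaError(
                f"non-finite value at row {r}, column {self.feature_names[c]!r}"
            )
        if self.subject_ids is not None:
            self.subject_ids = [str(s) for s in self.subject_ids]
            if len(self.subject_ids) != self.values.shape[0]:
                raise SchemaError("subject_ids must be one per row")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def subset(self, indices: np.ndarray | Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        ids = [self.subject_ids[i] for i in idx] if self.subject_ids else None
        return FeatureTable(self.values[idx], self.feature_names,
                            self.labels[idx], ids)

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = self.labels
        if self.subject_ids is not None:
            df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       id_column: str | None = None) -> "FeatureTable":
        if label_column not in df.columns:
            raise SchemaError(f"label column {label_column!r} not found")
        ids = None
        df = df.copy()
        if id_column is None and "subject_id" in df.columns:
            id_column = "subject_id"
        if id_column is not None and id_column in df.columns:
            ids = df.pop(id_column).astype(str).tolist()
        labels = df.pop(label_column).to_numpy()
        feature_names = [str(c) for c in df.columns]
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"missing value at row {row}, column {col!r}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError):
            for col in df.columns:
                coerced = pd.to_numeric(df[col], errors="coerce")
                if coerced.isna().any():
                    row = int(df.index[coerced.isna()][0])
                    raise SchemaError(
                        f"non-numeric value at row {row}, column {col!r}"
                    ) from None
            raise
        return cls(values, feature_names, labels, ids)

    def write_csv(self, path: str | Path, label_column: str = "label") -> None:
        self.to_dataframe(label_column).to_csv(path, index=False)


def read_table(path: str | Path, label_column: str = "label") -> FeatureTable:
    """Read and validate a cohort CSV.

    Fails loudly on a missing label column, non-numeric predictor cells
    (naming row and column) and missing values; no imputation is attempted.
    """
    df = pd.read_csv(path)
    return FeatureTable.from_dataframe(df, label_column=label_column)


def derive_ratios(table: FeatureTable) -> FeatureTable:
    """Append any absent ratio column (NEU/LY, PLT/LY, MPV/LY, LY/MO).

    Existing ratio columns are left untouched; a zero denominator is an
    error that names the offending rows.
    """
    values = table.values
    names = list(table.feature_names)
    new_cols = []
    for ratio, (num, den) in RATIO_DEFINITIONS.items():
        if ratio in names:
            continue
        if num not in names or den not in names:
            raise SchemaError(f"cannot derive {ratio!r}: missing {num!r} or {den!r}")
        d = table.column(den)
        zero_rows = np.flatnonzero(d == 0)
        if zero_rows.size:
            raise SchemaError(
                f"zero denominator {den!r} for ratio {ratio!r} at rows "
                f"{zero_rows[:10].tolist()}"
            )
        new_cols.append((ratio, table.column(num) / d))
    if not new_cols:
        return table
    extra = np.column_stack([c for _, c in new_cols])
    return FeatureTable(np.hstack([values, extra]),
                        names + [n for n, _ in new_cols],
                        table.labels, table.subject_ids)


@dataclass
class SplitAssignment:
    """Disjoint train/test row indices from a stratified split."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    test_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "seed": self.seed,
            "test_fraction": self.test_fraction,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["train_indices"], dtype=int),
                   np.asarray(d["test_indices"], dtype=int),
                   d["seed"], d["test_fraction"])


def largest_remainder_counts(class_sizes: Sequence[int],
                             fraction: float) -> list[int]:
    """Apportion round(total*fraction) test slots to classes.

    Each class's quota is ``size * fraction``; every class gets its floor and
    the remaining slots go to the largest fractional remainders (ties broken
    by class order).  This reproduces e.g. 477/504 at 0.2 -> 95 + 101 = 196.
    """
    sizes = np.asarray(class_sizes, dtype=float)
    total = int(np.floor(sizes.sum() * fraction + 0.5))
    quotas = sizes * fraction
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        for k in order[:remainder]:
            counts[k] += 1
    elif remainder < 0:
        order = np.argsort(quotas - counts, kind="stable")
        for k in order[:-remainder]:
            counts[k] -= 1
    return counts.tolist()


def stratified_split(table: FeatureTable, test_fraction: float = 0.2,
                     seed: int = 0) -> SplitAssignment:
    """Stratified train/test split preserving class balance.

    Per-class test counts follow largest-remainder apportionment of
    ``test_fraction``; within each class the selection is uniform at random
    under ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    classes = [0, 1]
    class_rows = [np.flatnonzero(table.labels == c) for c in classes]
    for c, rows in zip(classes, class_rows):
        if rows.size == 0:
            raise ValueError(f"class {c} has no rows; cannot stratify")
    counts = largest_remainder_counts([r.size for r in class_rows],
                                      test_fraction)
    rng = np.random.default_rng(seed)
    test_parts, train_parts = [], []
    for rows, k in zip(class_rows, counts):
        perm = rng.permutation(rows)
        test_parts.append(perm[:k])
        train_parts.append(perm[k:])
    test_idx = np.sort(np.concatenate(test_parts))
    train_idx = np.sort(np.concatenate(train_parts))
    return SplitAssignment(train_idx, test_idx, seed, test_fraction)


@dataclass
class StandardizationParams:
    """Per-feature mean and population SD (divisor n), fitted on training rows."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "feature_names": self.feature_names,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]),
                   d["feature_names"])


def fit_standardizer(table: FeatureTable,
                     train_indices: np.ndarray | None = None
                     ) -> StandardizationParams:
    """Fit z-score parameters on the given rows (all rows if None).

    Uses the population SD (divisor n).  A constant training column is an
    error naming the feature.
    """
    rows = table.values if train_indices is None else table.values[np.asarray(train_indices, dtype=int)]
    mean = rows.mean(axis=0)
    std = rows.std(axis=0)  # ddof=0
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ValueError(
            f"constant training column(s): "
            f"{[table.feature_names[i] for i in zero]}"
        )
    return StandardizationParams(mean, std, list(table.feature_names))


def apply_standardizer(params: StandardizationParams,
                       table: FeatureTable) -> FeatureTable:
    """Return a new table with z-scored values ``(x - mean) / std``."""
    if params.feature_names and params.feature_names != table.feature_names:
        raise SchemaError("feature names do not match the fitted standardizer")
    z = (table.values - params.mean) / params.std
    return FeatureTable(z, table.feature_names, table.labels,
                        table.subject_ids)


def invert_standardizer(params: StandardizationParams,
                        table: FeatureTable) -> FeatureTable:
    """Undo :func:`apply_standardizer` (identity within float rounding)."""
    x = table.values * params.std + params.mean
    return FeatureTable(x, table.feature_names, table.labels,
                        table.subject_ids)
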