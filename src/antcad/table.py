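"""Labeled feature tables: the substrate that feature selection operates on.

A :class:`FeatureTable` holds a dense ``n_samples x n_features`` real matrix,
an optional categorical label vector, and string identifiers for features and
samples.  Tables round-trip through delimited text: a header row, a leading
``sample`` id column, numeric feature columns, and a ``label`` column when
labels are present.  Missing values are rejected — every downstream stage
(entropy estimation, cross-validation, pheromone deposits) assumes finite
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CategoricalSeries", "FeatureTable", "read_feature_csv", "write_feature_csv"]

LABEL_COLUMN = "label"
SAMPLE_COLUMN = "sample"


@dataclass(frozen=True)
class CategoricalSeries:
    """A discrete random variable: integer category codes plus category count.

    Parameters
    ----------
    codes
        Integer codes, one per observation; each must lie in
        ``[0, n_categories)``.
    n_categories
        Number of distinct categories the variable may take.  May exceed the
        number of codes actually observed.
    """

    codes: np.ndarray
    n_categories: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size < 1:
            raise ValueError("codes must be a non-empty 1-D sequence")
        if self.n_categories < 1:
            raise ValueError("n_categories must be positive")
        if codes.min() < 0 or codes.max() >= self.n_categories:
            raise ValueError("every code must lie in [0, n_categories)")

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass
class FeatureTable:
    """Samples-by-features matrix with optional class labels."""

    X: np.ndarray
    y: CategoricalSeries | None = None
    feature_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None
    class_names: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples x n_features)")
        n, f = self.X.shape
        if n < 1 or f < 1:
            raise ValueError("table must have at least one sample and one feature")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.y is not None and len(self.y) != n:
            raise ValueError("label length does not match sample count")
        if self.feature_ids is None:
            self.feature_ids = [f"f{j}" for j in range(f)]
        else:
            self.feature_ids = list(self.feature_ids)
            if len(self.feature_ids) != f:
                raise ValueError("feature_ids length does not match feature count")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match sample count")
        if self.class_names is not None:
            self.class_names = list(self.class_names)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        if self.y is None:
            raise ValueError("table has no labels")
        return self.y.n_categories

    def require_labels(self) -> CategoricalSeries:
        if self.y is None:
            raise ValueError("operation requires a labeled table")
        return self.y

    def select_features(self, indices: Sequence[int]) -> "FeatureTable":
        """Restrict the table to the given feature columns (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("cannot select an empty feature subset")
        return FeatureTable(
            X=self.X[:, idx],
            y=self.y,
            feature_ids=[self.feature_ids[j] for j in idx],
            sample_ids=self.sample_ids,
            class_names=self.class_names,
        )

    def take_samples(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        y = None
        if self.y is not None:
            y = CategoricalSeries(self.y.codes[idx], self.y.n_categories)
        return FeatureTable(
            X=self.X[idx],
            y=y,
            feature_ids=self.feature_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            class_names=self.class_names,
        )


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a table as delimited text: sample id, feature columns, label."""
    df = pd.DataFrame(table.X, columns=list(table.feature_ids))
    df.insert(0, SAMPLE_COLUMN, list(table.sample_ids))
    if table.y is not None:
        if table.class_names is not None:
            labels = [table.class_names[c] for c in table.y.codes]
        else:
            labels = table.y.codes.tolist()
        df[LABEL_COLUMN] = labels
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_csv`.

    The first column is the sample id; a column named ``label`` (if present)
    provides class labels, encoded to integer codes in sorted label order.
    Missing values anywhere are an error.
    """
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed in feature tables")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a sample-id column plus feature columns")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    df = df.iloc[:, 1:]
    y = None
    class_names = None
    if LABEL_COLUMN in df.columns:
        labels = df.pop(LABEL_COLUMN)
        cats = sorted(labels.astype(str).unique())
        lookup = {c: i for i, c in enumerate(cats)}
        codes = np.array([lookup[v] for v in labels.astype(str)], dtype=np.int64)
        y = CategoricalSeries(codes, len(cats))
        class_names = cats
    X = df.to_numpy(dtype=float)
    return FeatureTable(
        X=X,
        y=y,
        feature_ids=list(df.columns),
        sample_ids=sample_ids,
        class_names=class_names,
    )
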