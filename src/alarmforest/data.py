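"""Labelled feature tables for binary alarm classification.

A :class:`Dataset` pairs a numeric feature table with a YES/NO alarm label
per observation.  YES marks a true alarm (the positive class), NO a false
alarm.  Datasets are read and written as plain CSV with a header row and a
named label column.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE = "YES"
NEGATIVE = "NO"

DEFAULT_LABEL_COLUMN = "alarm"


def as_binary(labels) -> np.ndarray:
    """Coerce labels to a boolean array (True = YES, the positive class).

    Accepts YES/NO strings, booleans or 0/1 integers.
    """
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr.copy()
    if np.issubdtype(arr.dtype, np.number):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("numeric labels must be 0/1")
        return arr.astype(bool)
    out = np.empty(arr.shape, dtype=bool)
    for value, flag in ((POSITIVE, True), (NEGATIVE, False)):
        out[arr == value] = flag
    bad = ~np.isin(arr, (POSITIVE, NEGATIVE))
    if bad.any():
        raise ValueError(f"labels must be {POSITIVE}/{NEGATIVE}; got {arr[bad][:5]!r}")
    return out


def as_labels(flags) -> np.ndarray:
    """Boolean array back to YES/NO strings."""
    flags = np.asarray(flags, dtype=bool)
    return np.where(flags, POSITIVE, NEGATIVE)


@dataclass
class Dataset:
    """Feature table plus binary alarm outcome.

    Parameters
    ----------
    features : DataFrame, shape (n, p)
        Numeric predictors; the index provides stable observation ids.
    labels : Series of YES/NO
        Alarm outcome, aligned with ``features``.
    name : str
        Dataset identifier used in reports (e.g. the arrhythmia type).
    """

    features: pd.DataFrame
    labels: pd.Series
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.features = pd.DataFrame(self.features)
        self.labels = pd.Series(np.asarray(self.labels), index=self.features.index)
        if self.features.shape[0] < 2:
            raise ValueError("need at least two observations")
        if self.features.shape[1] < 1:
            raise ValueError("need at least one feature")
        if self.labels.isna().any():
            raise ValueError("missing labels are not allowed")
        y = as_binary(self.labels)
        if y.all() or not y.any():
            raise ValueError("both label levels (YES and NO) must be present")
        self.labels = pd.Series(as_labels(y), index=self.features.index)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def ids(self) -> pd.Index:
        return self.features.index

    @property
    def y(self) -> np.ndarray:
        """Boolean outcome array (True = YES)."""
        return as_binary(self.labels)

    def class_counts(self) -> dict:
        y = self.y
        return {NEGATIVE: int((~y).sum()), POSITIVE: int(y.sum())}

    def subset(self, positions) -> "Dataset":
        """New Dataset restricted to integer row positions (order kept)."""
        positions = np.asarray(positions)
        return Dataset(
            features=self.features.iloc[positions],
            labels=self.labels.iloc[positions],
            name=self.name,
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, label_column: str = DEFAULT_LABEL_COLUMN) -> None:
        table = self.features.copy()
        if label_column in table.columns:
            raise ValueError(f"feature column clashes with label column {label_column!r}")
        table[label_column] = self.labels
        table.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, label_column: str = DEFAULT_LABEL_COLUMN,
                 name: str | None = None) -> "Dataset":
        table = pd.read_csv(path, index_col=0)
        if label_column not in table.columns:
            raise ValueError(
                f"label column {label_column!r} not found in {path} "
                f"(columns: {list(table.columns)})"
            )
        labels = table[label_column]
        features = table.drop(columns=[label_column])
        if name is None:
            name = getattr(path, "stem", str(path))
        return cls(features=features, labels=labels, name=name)
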