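"""Labelled feature-matrix containers and loaders.

Every stage of the pipeline consumes a :class:`Dataset`: a dense
samples x features matrix ``X``, integer class labels ``y`` re-encoded
to ``0..k-1``, and unique feature names.  Distances are always measured
on min-max normalized columns (:func:`minmax_normalize`); rank
statistics are scale-invariant and use the raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mkmdigwo")

__all__ = ["Dataset", "NormalizedDataset", "read_csv", "read_svmlight", "minmax_normalize"]


@dataclass
class Dataset:
    """A labelled numeric feature matrix.

    Attributes
    ----------
    X : ndarray of shape (n_samples, n_features)
        Feature values, arbitrary units.
    y : ndarray of shape (n_samples,)
        Integer class labels in ``0..k-1``.
    feature_names : list of str
        Unique names, one per column.
    label_mapping : dict
        Original label value -> encoded integer (kept for reporting).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples x features matrix")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if len(self.y) != n:
            raise ValueError("label vector length does not match X")
        if np.unique(self.y).size < 2:
            raise ValueError("need at least 2 distinct class labels")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match X")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class NormalizedDataset:
    """Per-column min-max scaled view of a :class:`Dataset`.

    Non-constant columns span exactly [0, 1]; constant columns map to
    all-zero so their distance contribution vanishes.
    """

    X_norm: np.ndarray
    col_min: np.ndarray
    col_range: np.ndarray


def _encode_labels(raw: pd.Series) -> tuple[np.ndarray, dict]:
    classes, y = np.unique(raw.to_numpy(), return_inverse=True)
    mapping = {c: i for i, c in enumerate(classes)}
    logger.info("label encoding: %s", mapping)
    return y.astype(int), mapping


def read_csv(path, label_column: str) -> Dataset:
    """Load a header-row CSV with one row per sample.

    Parameters
    ----------
    path : str or path-like
    label_column : str
        Name of the class-label column; every other column must be numeric.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column]
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = coerced.isna() & ~feats[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric cell at row {row}, column {col!r}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"missing cell at row {row}, column {col!r}")
        feats[col] = coerced
    y, mapping = _encode_labels(labels)
    return Dataset(feats.to_numpy(dtype=float), y, [str(c) for c in feats.columns], mapping)


def read_svmlight(path) -> Dataset:
    """Load a sparse svmlight/LIBSVM file (1-based indices per that format)."""
    from sklearn.datasets import load_svmlight_file

    X, y_raw = load_svmlight_file(str(path))
    X = np.asarray(X.todense(), dtype=float)
    y, mapping = _encode_labels(pd.Series(y_raw))
    names = [f"f{j}" for j in range(X.shape[1])]
    return Dataset(X, y, names, mapping)


def minmax_normalize(d: Dataset | np.ndarray) -> NormalizedDataset:
    """Scale each column to [0, 1] by (v - min) / (max - min).

    Constant columns become all-zero.  Idempotent: applying it to its
    own output changes nothing.
    """
    X = d.X if isinstance(d, Dataset) else np.asarray(d, dtype=float)
    mins = X.min(axis=0)
    rng = X.max(axis=0) - mins
    safe = np.where(rng == 0, 1.0, rng)
    Xn = (X - mins) / safe
    Xn[:, rng == 0] = 0.0
    return NormalizedDataset(Xn, mins, rng)
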