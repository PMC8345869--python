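"""Wrapper fitness: grid-searched, stratified k-fold CV accuracy of an SVM.

The fitness of a feature subset is the best 10-fold cross-validated
accuracy over a (C, gamma) grid of a kernel SVM trained on the subset's
columns, reported in percent.  Min-max scaling is fit inside each
training fold and applied to its test fold (no leakage).  Folds are
fixed by a fold seed, making fitness a pure function of the subset --
required for memoization and for monotone best-so-far traces.  Ties in
fitness break toward the shorter subset; the grid winner maximizes the
same CV accuracy that is reported (no nested CV, so the reported
accuracy carries the usual optimistic selection bias).

Classifier training delegates to scikit-learn; this module owns only
the protocol (folds, grids, scaling hygiene, ordering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import total_ordering

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

logger = logging.getLogger("mkmdigwo")

__all__ = ["ClassifierConfig", "FitnessValue", "cv_accuracy", "compare", "memo_fitness"]

# the standard coarse LIBSVM-style grid
_DEFAULT_C = [2.0 ** k for k in range(-5, 16, 2)]
_DEFAULT_GAMMA = [2.0 ** k for k in range(-15, 4, 2)]
_FAST_C = [0.1, 1.0, 10.0, 100.0]
_FAST_GAMMA = [0.001, 0.01, 0.1, 1.0]


@dataclass
class ClassifierConfig:
    kernel: str = "rbf"  # linear | poly | rbf | sigmoid
    C_grid: list[float] = field(default_factory=lambda: list(_DEFAULT_C))
    gamma_grid: list[float] = field(default_factory=lambda: list(_DEFAULT_GAMMA))
    degree: int = 3
    coef0: float = 0.0
    n_folds: int = 10
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not self.C_grid or (self.kernel != "linear" and not self.gamma_grid):
            raise ValueError("parameter grids must be non-empty")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.kernel in ("poly", "rbf") and any(g <= 0 for g in self.gamma_grid):
            raise ValueError("gamma must be positive for poly/rbf kernels")

    @classmethod
    def fast(cls, **kw) -> "ClassifierConfig":
        """Coarse 4x4 grid profile for desk-scale runs."""
        kw.setdefault("C_grid", list(_FAST_C))
        kw.setdefault("gamma_grid", list(_FAST_GAMMA))
        return cls(**kw)


@total_ordering
@dataclass(frozen=True)
class FitnessValue:
    """CV accuracy (percent) with subset length as tie-break.

    Ordering: ``f1 > f2`` iff f1 is BETTER -- higher accuracy, or equal
    accuracy with a shorter subset.
    """

    accuracy: float
    subset_length: int
    C: float | None = None
    gamma: float | None = None

    def _key(self):
        return (self.accuracy, -self.subset_length)

    def __eq__(self, other) -> bool:
        return self._key() == other._key()

    def __lt__(self, other) -> bool:
        return self._key() < other._key()


def compare(f1: FitnessValue, f2: FitnessValue) -> int:
    """+1 if f1 is better, -1 if worse, 0 on a tie."""
    if f1 > f2:
        return 1
    if f1 < f2:
        return -1
    return 0


def _grid(cfg: ClassifierConfig):
    if cfg.kernel == "linear":
        return [(C, None) for C in cfg.C_grid]
    return [(C, g) for C in cfg.C_grid for g in cfg.gamma_grid]


def cv_accuracy(data, subset, cfg: ClassifierConfig) -> FitnessValue:
    """Grid-maximized stratified k-fold CV accuracy on the subset's columns."""
    subset = sorted(subset)
    if not subset:
        raise ValueError("empty feature subset")
    y = data.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n_folds = cfg.n_folds
    if counts.min() < n_folds:
        n_folds = max(2, int(counts.min()))
        logger.warning("smallest class has %d members; reducing to %d folds",
                       counts.min(), n_folds)
    X = data.X[:, subset]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.fold_seed)
    # scaling is fit per training fold, once, shared across the grid
    folds = []
    for train, test in skf.split(X, y):
        scaler = MinMaxScaler().fit(X[train])
        folds.append((scaler.transform(X[train]), y[train],
                      scaler.transform(X[test]), y[test]))

    best_acc, best_C, best_g = -1.0, None, None
    for C, g in _grid(cfg):
        svc_kw = dict(kernel=cfg.kernel, C=C)
        if g is not None:
            svc_kw["gamma"] = g
        if cfg.kernel == "poly":
            svc_kw["degree"] = cfg.degree
        if cfg.kernel in ("poly", "sigmoid"):
            svc_kw["coef0"] = cfg.coef0
        correct = 0
        for Xtr, ytr, Xte, yte in folds:
            clf = SVC(**svc_kw)
            clf.fit(Xtr, ytr)
            correct += int((clf.predict(Xte) == yte).sum())
        acc = 100.0 * correct / len(y)
        if acc > best_acc:
            best_acc, best_C, best_g = acc, C, g
    return FitnessValue(accuracy=best_acc, subset_length=len(subset),
                        C=best_C, gamma=best_g)


class _MemoizedFitness:
    """Caches fitness by the subset's index set; survives refilter phases."""

    def __init__(self, fn):
        self._fn = fn
        self.cache: dict[frozenset, object] = {}
        self.calls = 0
        self.hits = 0

    def __call__(self, subset):
        self.calls += 1
        key = frozenset(int(j) for j in subset)
        if key in self.cache:
            self.hits += 1
            return self.cache[key]
        value = self._fn(tuple(sorted(key)))
        self.cache[key] = value
        return value


def memo_fitness(fitness_fn) -> _MemoizedFitness:
    """Wrap a fitness function with a subset-keyed cache (hit/call counters)."""
    return _MemoizedFitness(fitness_fn)
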