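"""Euclidean-distance redundancy measures over normalized feature columns.

The redundancy half of the MKMD filter: a candidate far (in Euclidean
distance) from everything already selected adds the least-redundant
information.  MD1 is the max distance from one feature to a selected
set; MD2 maximizes MD1 over the candidate set.  Distances are computed
on min-max normalized columns so they share a scale with the Kendall
relevance term.
"""

from __future__ import annotations

import numpy as np

from .dataio import NormalizedDataset

__all__ = ["euclidean", "DistanceCache", "md1", "md2"]


def euclidean(u, v) -> float:
    """sqrt(sum (u_k - v_k)^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return float(np.linalg.norm(u - v))


class DistanceCache:
    """Pairwise column distances of a normalized matrix, computed on demand.

    One cache lives per filter pass; keys are unordered index pairs.
    """

    def __init__(self, data: NormalizedDataset):
        self._X = data.X_norm
        self._cache: dict[tuple[int, int], float] = {}

    def dist(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        d = self._cache.get(key)
        if d is None:
            d = euclidean(self._X[:, i], self._X[:, j])
            self._cache[key] = d
        return d


def _as_cache(data) -> DistanceCache:
    return data if isinstance(data, DistanceCache) else DistanceCache(data)


def md1(k: int, selected, data) -> tuple[float, int]:
    """Max distance from feature ``k`` to a selected set; returns (dist, argmax j)."""
    cache = _as_cache(data)
    selected = sorted(selected)
    if not selected:
        raise ValueError("selected set must be non-empty")
    best_j, best_d = selected[0], -1.0
    for j in selected:
        d = cache.dist(k, j)
        if d > best_d:
            best_j, best_d = j, d
    return best_d, best_j


def md2(selected, candidates, data) -> tuple[float, int]:
    """Max over candidates m of md1(m, selected); returns (dist, argmax m)."""
    cache = _as_cache(data)
    selected = sorted(selected)
    candidates = sorted(candidates)
    if not selected or not candidates:
        raise ValueError("both sets must be non-empty")
    if set(selected) & set(candidates):
        raise ValueError("selected and candidate sets must be disjoint")
    best_m, best_d = candidates[0], -1.0
    for m in candidates:
        d, _ = md1(m, selected, cache)
        if d > best_d:
            best_m, best_d = m, d
    return best_d, best_m
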