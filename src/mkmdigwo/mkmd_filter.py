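"""Greedy MKMD feature ranking under the quadratic a/b weight schedule.

Each greedy step scores a not-yet-selected feature j as

    a * MK(F_j, L) + b * MD(F_j, selected)

where MK is the absolute tie-corrected Kendall correlation with the
labels, MD the maximum normalized Euclidean distance to the already
selected set, and (a, b) = (1 - (t/T)^2, (t/T)^2) for the outer
iteration t at which the filter was invoked.  Early invocations weight
relevance; late invocations weight diversity (the weights cross between
t = 70 and 71 of 100).  The first pick is pure relevance (no selected
set exists yet), so every ranking starts at the argmax-tau feature.

Scoring the set-level MD per candidate inside the argmax is equivalent
to the set-to-set maximum distance, which already embeds that argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset, minmax_normalize
from .kendall import tau_abs
from .redundancy import DistanceCache, md1

__all__ = ["ScheduleWeights", "FeatureRanking", "ab_weights", "mkmd_score", "mkmd_rank"]

DEFAULT_RANK_BUDGET = 100  # top-K candidate subset handed to the wrapper


@dataclass(frozen=True)
class ScheduleWeights:
    """Relevance/redundancy mixing weights at outer iteration t of T."""

    a: float
    b: float
    t: int = 0
    T: int = 1


@dataclass
class FeatureRanking:
    """Greedy MKMD ordering with per-step scores."""

    order: list[int]
    scores: list[float]
    weights: ScheduleWeights
    feature_names: list[str]

    @property
    def candidate_subset(self) -> list[int]:
        return list(self.order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.order) + 1),
            "feature_index": self.order,
            "feature_name": [self.feature_names[j] for j in self.order],
            "score": self.scores,
            "a": self.weights.a,
            "b": self.weights.b,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ab_weights(t: int, T: int) -> ScheduleWeights:
    """a = 1 - (t/T)^2, b = (t/T)^2; a + b = 1 by construction."""
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    frac = (t / T) ** 2
    return ScheduleWeights(a=1.0 - frac, b=frac, t=t, T=T)


def mkmd_score(j: int, selected, w: ScheduleWeights, data: Dataset,
               _tau=None, _cache=None) -> float:
    """Score candidate j against the selected set under weights w.

    With no selected features the score is a*MK alone; otherwise
    a*MK + b*(max distance to the selected set).
    """
    selected = list(selected)
    if j in selected:
        raise ValueError(f"feature {j} already selected")
    mk = _tau[j] if _tau is not None else tau_abs(data.X[:, j], data.y)
    if not selected:
        return w.a * mk
    cache = _cache if _cache is not None else DistanceCache(minmax_normalize(data))
    d, _ = md1(j, selected, cache)
    return w.a * mk + w.b * d


def mkmd_rank(data: Dataset, w: ScheduleWeights, K: int | None = None) -> FeatureRanking:
    """Rank the top-K features by greedy MKMD selection.

    Deterministic given (data, w, K); ties break toward the lowest
    feature index.  K defaults to min(100, n_features): only the top-K
    candidate subset feeds the wrapper, so ranking the full feature set
    is wasted work (a caller may pass K=n_features to rank everything).
    """
    p = data.n_features
    if K is None:
        K = min(DEFAULT_RANK_BUDGET, p)
    if K < 1:
        raise ValueError("K must be >= 1")
    K = min(K, p)

    tau = np.array([tau_abs(data.X[:, j], data.y) for j in range(p)])
    cache = DistanceCache(minmax_normalize(data))

    order: list[int] = []
    scores: list[float] = []
    remaining = list(range(p))
    for _ in range(K):
        best_j, best_s = remaining[0], -np.inf
        for j in remaining:
            s = mkmd_score(j, order, w, data, _tau=tau, _cache=cache)
            if s > best_s:
                best_j, best_s = j, s
        order.append(best_j)
        scores.append(best_s)
        remaining.remove(best_j)
    return FeatureRanking(order=order, scores=scores, weights=w,
                          feature_names=list(data.feature_names))
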