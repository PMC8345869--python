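"""Kendall rank correlation with tie corrections, and the maximum-relevance pick.

The relevance half of the MKMD filter.  The statistic used throughout is
the absolute tie-corrected coefficient

    T(X, Y) = |C - D| / sqrt((N3 - N1)(N3 - N2)),

i.e. |tau-b|, where C / D count concordant / discordant index pairs, N3 =
N(N-1)/2 and N1, N2 are the per-vector tie corrections sum u_i(u_i-1)/2
over tie groups.  Counts are exact integers; only the final ratio is
floating point.  Pair counting is O(N^2) by design -- N is a sample
count, small, and the quadratic form is trivially verifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("mkmdigwo")

__all__ = ["PairCounts", "pair_counts", "tie_correction", "tau_t1", "tau_abs", "max_kendall"]


@dataclass(frozen=True)
class PairCounts:
    """Concordant/discordant pair counts and tie terms for one vector pair."""

    C: int
    D: int
    N: int
    N1: int
    N2: int
    N3: int
    tie_groups_x: tuple[int, ...]
    tie_groups_y: tuple[int, ...]


def _tie_groups(v: np.ndarray) -> tuple[int, ...]:
    # groups of exactly-equal values with multiplicity >= 2
    _, counts = np.unique(v, return_counts=True)
    return tuple(int(c) for c in counts if c >= 2)


def tie_correction(v) -> int:
    """Sum of u(u-1)/2 over groups of equal values in ``v``."""
    v = np.asarray(v)
    if v.size < 2:
        raise ValueError("need at least 2 elements")
    return sum(u * (u - 1) // 2 for u in _tie_groups(v))


def pair_counts(x, y) -> PairCounts:
    """Count concordant and discordant pairs of (x_i, y_i) vs (x_j, y_j).

    A pair (i < j) is concordant when x and y order it the same way and
    discordant when they order it oppositely; pairs tied in either
    vector count toward neither.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 elements")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(n, k=1)
    C = int(np.count_nonzero(prod[iu] > 0))
    D = int(np.count_nonzero(prod[iu] < 0))
    gx, gy = _tie_groups(x), _tie_groups(y)
    n1 = sum(u * (u - 1) // 2 for u in gx)
    n2 = sum(u * (u - 1) // 2 for u in gy)
    return PairCounts(C=C, D=D, N=n, N1=n1, N2=n2, N3=n * (n - 1) // 2,
                      tie_groups_x=gx, tie_groups_y=gy)


def tau_t1(x, y) -> float:
    """Plain Kendall coefficient 2(C - D)/(N(N-1)); requires tie-free vectors."""
    pc = pair_counts(x, y)
    if pc.N1 or pc.N2:
        raise ValueError("ties present; use the tie-corrected statistic (tau_abs)")
    return 2.0 * (pc.C - pc.D) / (pc.N * (pc.N - 1))


def tau_abs(x, y) -> float:
    """Absolute tie-corrected Kendall coefficient |C-D|/sqrt((N3-N1)(N3-N2)).

    A constant vector makes the denominator vanish; such a feature
    carries no rank information, so 0 is returned (with a warning)
    rather than raising, keeping greedy ranking total.
    """
    pc = pair_counts(x, y)
    denom_sq = (pc.N3 - pc.N1) * (pc.N3 - pc.N2)
    if denom_sq == 0:
        logger.warning("constant vector in Kendall computation; returning 0")
        return 0.0
    return abs(pc.C - pc.D) / float(np.sqrt(denom_sq))


def max_kendall(data, candidates) -> tuple[int, float]:
    """Pick the candidate feature most rank-correlated with the labels.

    Returns ``(index, score)`` maximizing ``tau_abs(X[:, j], y)``;
    ties break toward the lowest index.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    best_j, best_s = candidates[0], -1.0
    for j in candidates:
        s = tau_abs(data.X[:, j], data.y)
        if s > best_s:
            best_j, best_s = j, s
    return best_j, best_s
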