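"""Binary grey-wolf optimization over feature-subset bitmasks.

A pack of wolves carries binary positions (bit d = feature d of the
candidate subset is in the wolf's subset).  The three best-so-far
solutions (alpha, beta, delta) lead; each leader contributes a binary
vote per dimension built from the continuous encircling machinery
(coefficients A = 2*a*r1 - a, C = 2*r2 with a decreasing linearly 2 -> 0,
leader distance D = |C*x_leader - x|, squashed through a steep sigmoid
into a stochastic step).  The improved update aggregates the three
votes through a trigonometric majority gate

    thrg(x1, x2, x3) = 1  iff  |x1 + x2 + x3| > 3 sin(x),  x ~ U(0, pi/2)

and mixes it with the wolf's previous position:

    v = t1 * thrg + t2 * x_prev,   t1 = t sin(x),  t2 = 1 - 4 t sin(x)

with t = (T - l)/T decaying over iterations, so late iterations freeze
positions (t1 -> 0, t2 -> 1).  t2 may be negative early on; the
binarization threshold absorbs that, which acts as aggressive early
exploration.  The two classic binary update rules (per-dimension leader
roulette, and a sigmoid transfer on the leader mean) are available
behind the same interface for comparison.

Leaders are elitist (best-so-far over the run), so the best-fitness
trace is non-decreasing.  Wolves whose subset empties are repaired by
switching one uniformly chosen bit on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("mkmdigwo")

__all__ = ["IGWOConfig", "WolfPack", "BinaryGWO", "decay", "bstep_draw",
           "leader_bits", "thrg", "run_igwo"]


@dataclass
class IGWOConfig:
    n_wolves: int = 30
    update_rule: str = "improved"  # improved | bgwo1 | bgwo2
    binarization_threshold: float = 0.5
    stochastic_binarization: bool = False

    def __post_init__(self) -> None:
        if self.n_wolves < 3:
            raise ValueError("need at least 3 wolves (alpha/beta/delta)")
        if self.update_rule not in ("improved", "bgwo1", "bgwo2"):
            raise ValueError(f"unknown update rule {self.update_rule!r}")


def decay(l: int, T: int) -> float:
    """Linear decay (T - l)/T from 1 to 0 over the iteration budget."""
    if not 0 <= l <= T:
        raise ValueError("iteration outside budget")
    return (T - l) / T


def _steep_sigmoid(v):
    return 1.0 / (1.0 + np.exp(-10.0 * (v - 0.5)))


def bstep_draw(ad: float, rng) -> int:
    """Stochastic binary step: 1 iff sigmoid-squashed A*D beats a uniform draw."""
    cstep = float(_steep_sigmoid(ad))
    return 1 if cstep >= rng.random() else 0


def leader_bits(leader_bit: int, wolf_bit: int, a_lin: float, rng) -> int:
    """One leader's binary vote for one dimension.

    Draws fresh r1, r2 (and the step's uniform) per call; the continuous
    step size A*D is squashed to cstep, thresholded stochastically to
    bstep, and the vote is 1 iff leader_bit + bstep >= 1.
    """
    r1, r2 = rng.random(), rng.random()
    A = 2.0 * a_lin * r1 - a_lin
    C = 2.0 * r2
    D = abs(C * leader_bit - wolf_bit)
    bstep = bstep_draw(A * D, rng)
    return 1 if leader_bit + bstep >= 1 else 0


def thrg(x1: int, x2: int, x3: int, rng) -> int:
    """Trigonometric three-leader gate; draws its own x ~ U(0, pi/2)."""
    x = rng.random() * (np.pi / 2.0)
    return 1 if abs(x1 + x2 + x3) > 3.0 * np.sin(x) else 0


@dataclass
class WolfPack:
    """Binary positions plus elitist leader bookkeeping."""

    positions: np.ndarray  # (n_wolves, dim) in {0, 1}
    fitness: list = field(default_factory=list)  # per-wolf, this generation
    leader_positions: list = field(default_factory=list)  # [alpha, beta, delta]
    leader_fitness: list = field(default_factory=list)


class BinaryGWO:
    """Stepwise binary GWO engine over ``dim``-bit masks.

    ``fitness_fn`` maps a tuple of set bit indices (candidate-space) to
    any orderable value; larger is better.  The engine is driven by
    :meth:`initialize` then repeated :meth:`step` calls, which lets an
    outer controller interleave restarts with a shared iteration budget.
    """

    def __init__(self, dim: int, fitness_fn, cfg: IGWOConfig, rng: np.random.Generator):
        if dim < 1:
            raise ValueError("dimension must be >= 1")
        self.dim = dim
        self.fitness_fn = fitness_fn
        self.cfg = cfg
        self.rng = rng
        self.pack: WolfPack | None = None

    # -- population management -------------------------------------------

    def _repair(self, positions: np.ndarray) -> np.ndarray:
        empty = np.flatnonzero(positions.sum(axis=1) == 0)
        for i in empty:
            positions[i, self.rng.integers(self.dim)] = 1
        return positions

    def initialize(self) -> None:
        pos = (self.rng.random((self.cfg.n_wolves, self.dim)) < 0.5).astype(np.int8)
        pos = self._repair(pos)
        self.pack = WolfPack(positions=pos)
        self._evaluate()

    def _evaluate(self) -> None:
        pack = self.pack
        pack.fitness = [self.fitness_fn(tuple(np.flatnonzero(w))) for w in pack.positions]
        # merge this generation into the best-so-far leader triple
        entries = list(zip(pack.leader_fitness, pack.leader_positions))
        entries += [(f, p.copy()) for f, p in zip(pack.fitness, pack.positions)]
        entries.sort(key=_SortKey, reverse=True)
        kept, seen = [], set()
        for f, p in entries:
            key = p.tobytes()
            if key in seen:
                continue
            seen.add(key)
            kept.append((f, p))
            if len(kept) == 3:
                break
        while len(kept) < 3:  # degenerate tiny search spaces
            kept.append(kept[-1])
        pack.leader_fitness = [f for f, _ in kept]
        pack.leader_positions = [p for _, p in kept]

    # -- position updates -------------------------------------------------

    def _leader_votes(self, wolf: np.ndarray, a_lin: float) -> list[np.ndarray]:
        votes = []
        for lead in self.pack.leader_positions:
            r1 = self.rng.random(self.dim)
            r2 = self.rng.random(self.dim)
            A = 2.0 * a_lin * r1 - a_lin
            C = 2.0 * r2
            D = np.abs(C * lead - wolf)
            cstep = _steep_sigmoid(A * D)
            bstep = (cstep >= self.rng.random(self.dim)).astype(np.int8)
            votes.append(((lead + bstep) >= 1).astype(np.int8))
        return votes

    def step(self, l: int, T: int) -> None:
        """One generation: update every wolf's position, repair, evaluate."""
        if self.pack is None:
            raise RuntimeError("call initialize() first")
        t = decay(l, T)
        a_lin = 2.0 * t
        cfg = self.cfg
        new = np.empty_like(self.pack.positions)
        for i, wolf in enumerate(self.pack.positions):
            x1, x2, x3 = self._leader_votes(wolf, a_lin)
            if cfg.update_rule == "bgwo1":
                r = self.rng.random(self.dim)
                new[i] = np.where(r < 1 / 3, x1, np.where(r < 2 / 3, x2, x3))
            elif cfg.update_rule == "bgwo2":
                s = _steep_sigmoid((x1 + x2 + x3) / 3.0)
                new[i] = (s >= self.rng.random(self.dim)).astype(np.int8)
            else:
                x_shared = self.rng.random() * (np.pi / 2.0)
                t1 = np.sin(x_shared) * t
                t2 = 1.0 - 4.0 * t * np.sin(x_shared)
                xdraw = self.rng.random(self.dim) * (np.pi / 2.0)
                gate = (np.abs(x1 + x2 + x3) > 3.0 * np.sin(xdraw)).astype(np.int8)
                v = t1 * gate + t2 * wolf
                if cfg.stochastic_binarization:
                    new[i] = (_steep_sigmoid(v) >= self.rng.random(self.dim)).astype(np.int8)
                else:
                    new[i] = (v >= cfg.binarization_threshold).astype(np.int8)
        self.pack.positions = self._repair(new)
        self._evaluate()

    # -- results -----------------------------------------------------------

    @property
    def best_fitness(self):
        return self.pack.leader_fitness[0]

    @property
    def best_position(self) -> np.ndarray:
        return self.pack.leader_positions[0]


class _SortKey:
    """Sort adapter: orders (fitness, position) pairs by fitness only."""

    __slots__ = ("f",)

    def __init__(self, entry):
        self.f = entry[0]

    def __lt__(self, other) -> bool:
        return self.f < other.f


def run_igwo(data, candidate, fitness_fn, cfg: IGWOConfig, budget: int,
             rng: np.random.Generator | None = None, seed: int | None = None):
    """Run the optimizer over a candidate feature list for ``budget`` iterations.

    ``fitness_fn`` receives subsets as tuples of ORIGINAL feature
    indices.  Returns ``(best subset original indices, best fitness,
    per-iteration best-fitness trace)``; the trace is non-decreasing by
    elitism.  ``data`` is accepted for interface symmetry with the rest
    of the pipeline and passed through to ``fitness_fn`` closures.
    """
    candidate = list(candidate)
    if not candidate:
        raise ValueError("candidate list must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    index_map = np.asarray(candidate)

    def local_fitness(bits: tuple) -> object:
        return fitness_fn(tuple(int(index_map[b]) for b in bits))

    engine = BinaryGWO(len(candidate), local_fitness, cfg, rng)
    engine.initialize()
    trace = [engine.best_fitness]
    for l in range(budget):
        engine.step(l, max(budget, 1))
        trace.append(engine.best_fitness)
    best_bits = np.flatnonzero(engine.best_position)
    best_subset = sorted(int(index_map[b]) for b in best_bits)
    return best_subset, engine.best_fitness, trace
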