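"""The outer loop wiring filter, optimizer, fitness, and restart controller.

One global iteration t of the run is: (1) ask the oscillation
controller whether to re-run the MKMD filter -- if so, re-rank under
the weights a(t), b(t), hand the top-K candidate subset to a freshly
initialized wolf pack, and reset the patience counter; (2) advance the
optimizer one generation, scoring wolves with memoized CV-accuracy
fitness; (3) compare the pack's best with the global best (accuracy
first, then subset length -- a length-only improvement counts), update
the patience counter; (4) record a trace row.  The global best is
archived in original feature indices, so it survives refilter phases,
and the fitness cache is keyed the same way, so phases share it.

All randomness flows from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import Dataset, read_csv
from .fitness import ClassifierConfig, FitnessValue, compare, cv_accuracy, memo_fitness
from .igwo import BinaryGWO, IGWOConfig
from .mkmd_filter import ab_weights, mkmd_rank
from .oscillator import OscillatorState, should_refilter, update_savemax

logger = logging.getLogger("mkmdigwo")

__all__ = ["RunConfig", "SelectionResult", "run_mkmdigwo", "repeated_runs"]


@dataclass
class RunConfig:
    data_path: str | None = None
    label_column: str = "label"
    T: int = 100
    n_wolves: int = 30
    K: int = 100
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    update_rule: str = "improved"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("iteration budget T must be >= 1")
        if self.K < 1:
            raise ValueError("candidate size K must be >= 1")


@dataclass
class SelectionResult:
    best_subset: list[int]
    best_feature_names: list[str]
    accuracy: float
    subset_length: int
    best_params: dict
    trace: pd.DataFrame
    seed: int
    n_refilters: int
    cache_stats: dict
    last_ranking: object = None

    def to_dict(self) -> dict:
        return {
            "best_subset": self.best_subset,
            "best_feature_names": self.best_feature_names,
            "accuracy": self.accuracy,
            "subset_length": self.subset_length,
            "best_params": self.best_params,
            "seed": self.seed,
            "n_refilters": self.n_refilters,
            "cache_stats": self.cache_stats,
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "result.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.trace.to_csv(out / "trace.csv", index=False)
        if self.last_ranking is not None:
            self.last_ranking.to_csv(out / "ranking.csv")


def run_mkmdigwo(cfg: RunConfig, dataset: Dataset | None = None) -> SelectionResult:
    """Execute one full selection run; deterministic given (data, cfg)."""
    if dataset is None:
        if cfg.data_path is None:
            raise ValueError("either a dataset or cfg.data_path is required")
        dataset = read_csv(cfg.data_path, cfg.label_column)
    logger.info("run: seed=%d T=%d wolves=%d K=%d kernel=%s", cfg.seed, cfg.T,
                cfg.n_wolves, cfg.K, cfg.classifier.kernel)

    rng = np.random.default_rng(cfg.seed)
    osc = OscillatorState.initialize(cfg.T, rng)
    memo = memo_fitness(lambda subset: cv_accuracy(dataset, subset, cfg.classifier))
    igwo_cfg = IGWOConfig(n_wolves=cfg.n_wolves, update_rule=cfg.update_rule)

    best: FitnessValue | None = None
    best_subset: list[int] = []
    engine: BinaryGWO | None = None
    index_map: np.ndarray | None = None
    ranking = None
    n_refilters = 0
    rows = []

    for t in range(cfg.T):
        refilter = should_refilter(osc)
        if refilter:
            w = ab_weights(t, cfg.T)
            ranking = mkmd_rank(dataset, w, cfg.K)
            index_map = np.asarray(ranking.order)
            local = _map_fitness(memo, index_map)
            engine = BinaryGWO(len(index_map), local, igwo_cfg, rng)
            engine.initialize()
            osc.mark_refiltered()
            n_refilters += 1
            logger.info("iter %d: refilter (a=%.3f b=%.3f), %d candidates",
                        t, w.a, w.b, len(index_map))

        engine.step(t, cfg.T)

        phase_best = engine.best_fitness
        improved = best is None or compare(phase_best, best) > 0
        if improved:
            best = phase_best
            bits = np.flatnonzero(engine.best_position)
            best_subset = sorted(int(index_map[b]) for b in bits)
        update_savemax(osc, improved)

        rows.append({
            "iteration": t,
            "best_acc": best.accuracy,
            "best_len": best.subset_length,
            "savemax": osc.savemax,
            "threshold": osc.active_threshold,
            "refilter": refilter,
        })

    trace = pd.DataFrame(rows)
    result = SelectionResult(
        best_subset=best_subset,
        best_feature_names=[dataset.feature_names[j] for j in best_subset],
        accuracy=best.accuracy,
        subset_length=best.subset_length,
        best_params={"C": best.C, "gamma": best.gamma},
        trace=trace,
        seed=cfg.seed,
        n_refilters=n_refilters,
        cache_stats={"calls": memo.calls, "hits": memo.hits,
                     "entries": len(memo.cache)},
        last_ranking=ranking,
    )
    if cfg.out_dir:
        result.save(cfg.out_dir)
    return result


def _map_fitness(memo, index_map: np.ndarray):
    def local(bits: tuple) -> FitnessValue:
        return memo(tuple(int(index_map[b]) for b in bits))
    return local


def repeated_runs(cfg: RunConfig, n_repeats: int = 10,
                  dataset: Dataset | None = None) -> dict:
    """Repeat the run with seeds derived from the master seed; summarize.

    Reports both the subset length of the best-accuracy run and the mean
    length across runs (the two natural readings of a per-dataset
    average length).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(n_repeats) % (2 ** 31)
    results = []
    for s in child_seeds:
        sub = dataclasses.replace(cfg, seed=int(s), out_dir=None)
        results.append(run_mkmdigwo(sub, dataset=dataset))
    accs = [r.accuracy for r in results]
    lens = [r.subset_length for r in results]
    i_best = max(range(n_repeats),
                 key=lambda i: (accs[i], -lens[i]))
    return {
        "max_acc": max(accs),
        "mean_acc": float(np.mean(accs)),
        "len_of_max_run": lens[i_best],
        "mean_len": float(np.mean(lens)),
        "runs": results,
    }
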