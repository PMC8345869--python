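"""Damped-oscillation restart schedule and the savemax patience controller.

The schedule

    y(t) = ceil(|2 e^(2 - t/60) cos(t/6)|) + ceil(5 u),   u ~ U(0, 1)

is a decaying-envelope cosine with a small random lift, evaluated at
integer iterations t = 0..100.  Its deterministic envelope has exactly
six local maxima on [0, 100] (at t = 0 and near every half-period of
the cosine); the y values at those six times, consumed in time order,
act as patience thresholds: when the run has gone ``savemax``
consecutive iterations without improving and savemax strictly exceeds
the current threshold, the controller orders a filter re-run and a
population restart.  Early thresholds are large (slow to restart while
exploration still pays), late ones small (restart quickly near the
end).  savemax starts at a sentinel of 100 so the first iteration
always runs the filter.

The random lift is drawn once per peak at extraction, so each phase has
a fixed threshold; a per-iteration redraw mode is available.  The six
deterministic peak heights sum to 49 and each lift is at most 5, so the
six thresholds always sum below 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = ["envelope", "damping_y", "envelope_peak_times", "extract_peaks",
           "OscillatorState", "should_refilter", "update_savemax"]

INITIAL_SAVEMAX = 100  # sentinel: forces the filter on the first iteration


def envelope(t) -> np.ndarray | float:
    """Deterministic part |2 e^(2 - t/60) cos(t/6)| of the schedule."""
    t = np.asarray(t, dtype=float)
    out = np.abs(2.0 * np.exp(2.0 - t / 60.0) * np.cos(t / 6.0))
    return float(out) if out.ndim == 0 else out


def _positive_uniform(rng) -> float:
    u = rng.random()
    while u == 0.0:  # ceil(5u) must be >= 1
        u = rng.random()
    return u


def damping_y(t: int, rng) -> int:
    """Schedule value at integer time t: ceil(envelope) + ceil(5 u)."""
    if not 0 <= t <= 100:
        raise ValueError("t must lie in [0, 100]")
    return int(np.ceil(envelope(t))) + int(np.ceil(5.0 * _positive_uniform(rng)))


def envelope_peak_times(T: int = 100) -> list[int]:
    """Integer times nearest the local maxima of the envelope on [0, T].

    t = 0 is a peak (the envelope decreases from it); interior peaks sit
    near every half-period of the cosine, pulled slightly left by the
    decaying exponential.
    """
    grid = np.linspace(0.0, T, 20 * T + 1)
    vals = envelope(grid)
    idx, _ = find_peaks(vals)
    times = list(grid[idx])
    if vals[0] > vals[1]:
        times.insert(0, 0.0)
    return [int(round(t)) for t in times]


def extract_peaks(T: int = 100, rng=None) -> list[int]:
    """Schedule values at the envelope's peak times, in time order."""
    if rng is None:
        rng = np.random.default_rng()
    return [damping_y(t, rng) for t in envelope_peak_times(T)]


@dataclass
class OscillatorState:
    """Peak thresholds, the consumption pointer, and the patience counter."""

    y_values: list[int]
    peaks: list[int]
    peak_times: list[int]
    peak_pointer: int = 0
    savemax: int = INITIAL_SAVEMAX

    @classmethod
    def initialize(cls, T: int = 100, rng=None) -> "OscillatorState":
        if rng is None:
            rng = np.random.default_rng()
        horizon = min(T, 100)
        y_values = [damping_y(t, rng) for t in range(horizon + 1)]
        times = [t for t in envelope_peak_times(horizon)]
        peaks = [damping_y(t, rng) for t in times]
        return cls(y_values=y_values, peaks=peaks, peak_times=times)

    @property
    def active_threshold(self) -> int | None:
        if self.peak_pointer >= len(self.peaks):
            return None
        return self.peaks[self.peak_pointer]

    def mark_refiltered(self) -> None:
        """Consume the current peak after a filter re-run."""
        self.savemax = 0
        self.peak_pointer += 1


def should_refilter(state: OscillatorState) -> bool:
    """True iff savemax strictly exceeds the current (unconsumed) threshold.

    Once all peaks are consumed the answer is always False.
    """
    thr = state.active_threshold
    return thr is not None and state.savemax > thr


def update_savemax(state: OscillatorState, improved: bool) -> OscillatorState:
    """Reset the patience counter to 1 on improvement, else increment it."""
    state.savemax = 1 if improved else state.savemax + 1
    return state
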