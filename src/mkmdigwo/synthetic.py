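"""Seeded generators of class-labelled matrices with known structure.

The generator emulates the structure the filter and wrapper are built to
exploit, at desk scale: informative columns whose class-conditional
means are shifted by a separation delta, redundant columns that are
near-copies (Gaussian jitter sigma_r) of informative columns, and
label-independent Gaussian noise columns.  The ground-truth partition is
returned with the data so recovery tests never re-derive it.

Also provides the small printed vectors used as worked examples for the
rank-correlation and distance statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset

__all__ = ["SyntheticSpec", "GroundTruth", "make_dataset", "write_csv",
           "worked_example_fixtures"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 100
    n_classes: int = 2
    n_informative: int = 5
    n_redundant: int = 10
    n_noise: int = 35
    delta: float = 1.5     # class-mean shift per informative feature
    sigma_r: float = 0.1   # jitter sd of redundant near-copies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")
        if min(self.n_redundant, self.n_noise) < 0 or self.n_classes < 2:
            raise ValueError("invalid counts")
        if self.sigma_r <= 0 or self.delta <= 0:
            raise ValueError("sigma_r and delta must be positive")


@dataclass(frozen=True)
class GroundTruth:
    informative: tuple[int, ...]
    redundant: tuple[int, ...]
    noise: tuple[int, ...]
    parent_of: dict  # redundant column index -> informative parent index


def make_dataset(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Sample one labelled matrix; columns ordered informative, redundant, noise."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_classes
    y = rng.permutation(np.arange(n) % k)

    cols, names = [], []
    informative = tuple(range(spec.n_informative))
    for j in informative:
        cols.append(rng.normal(y * spec.delta, 1.0))
        names.append(f"inf{j}")

    redundant, parent_of = [], {}
    for r in range(spec.n_redundant):
        parent = informative[r % spec.n_informative]
        idx = len(cols)
        cols.append(cols[parent] + rng.normal(0.0, spec.sigma_r, n))
        names.append(f"red{r}_of_inf{parent}")
        redundant.append(idx)
        parent_of[idx] = parent

    noise = []
    for m in range(spec.n_noise):
        noise.append(len(cols))
        cols.append(rng.normal(0.0, 1.0, n))
        names.append(f"noise{m}")

    data = Dataset(np.column_stack(cols), y, names)
    truth = GroundTruth(informative=informative, redundant=tuple(redundant),
                        noise=tuple(noise), parent_of=parent_of)
    return data, truth


def write_csv(data: Dataset, path, label_column: str = "label") -> None:
    """Write a Dataset in the CSV dialect the loader reads back."""
    df = pd.DataFrame(data.X, columns=data.feature_names)
    df[label_column] = data.y
    df.to_csv(path, index=False)


def worked_example_fixtures() -> dict[str, np.ndarray]:
    """The small printed vectors used as worked examples in tests.

    X, Y: 23-element integer label/feature pair with heavy ties.
    X1, Y1: 10-element pair, X1 with ties, Y1 real-valued and distinct.
    F1, F2: 23-element feature pair for the normalized-distance example.
    """
    return {
        "X": np.array([4, 1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 3, 4, 1, 2, 2, 2, 2, 3, 3, 5, 5, 5]),
        "Y": np.array([4, 4, 0, 4, 4, 4, 4, 0, 0, 4, 4, 2, 0, 0, 4, 6, 2, 4, 0, 0, 2, 2, 4]),
        "X1": np.array([1, 2, 3, 4, 5, 6, 2, 4, 6, 3]),
        "Y1": np.array([0.6, 1.8, 5.4, 3.9, 7.0, 10.0, 1.85, 4.0, 9.8, 5.7]),
        "F1": np.array([1, 5, 1, 1, 1, 1, 1, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2]),
        "F2": np.array([1, 4, 2, 2, 1, 2, 2, 2, 1, 1, 2, 1, 2, 2, 2, 1, 2, 1, 1, 2, 1, 1, 1]),
    }
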