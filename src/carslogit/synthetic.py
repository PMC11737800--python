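"""Seeded generator of binary-predictor / binary-response datasets.

Predictors are independent Bernoulli columns with per-column success
probabilities drawn uniformly from a configurable range; the response is
Bernoulli through a logistic link, either independent of the predictors
(null scenario) or driven by a planted set of informative columns whose
indices are returned as ground truth for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
import pandas as pd

from .data_model import Dataset

__all__ = [
    "SimConfig",
    "generate",
    "paper_scale_fixture",
    "recovery_fixture",
    "stratified_split",
    "write_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    ``informative_indices`` (0-based) and ``effect_sizes`` plant a
    log-odds effect per column; empty means the null scenario where the
    response is independent of every predictor.
    """

    n_samples: int = 5000
    n_variables: int = 100
    predictor_prob_range: tuple = (0.2, 0.8)
    informative_indices: tuple = ()
    effect_sizes: tuple = ()
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.predictor_prob_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("predictor_prob_range must lie strictly inside (0, 1)")
        if self.n_samples < 1 or self.n_variables < 1:
            raise ValueError("n_samples and n_variables must be positive")
        if len(self.informative_indices) != len(self.effect_sizes):
            raise ValueError("informative_indices and effect_sizes must have equal length")
        for j in self.informative_indices:
            if not 0 <= j < self.n_variables:
                raise ValueError(f"informative index {j} outside [0, {self.n_variables})")

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_variables": self.n_variables,
            "predictor_prob_range": list(self.predictor_prob_range),
            "informative_indices": list(self.informative_indices),
            "effect_sizes": list(self.effect_sizes),
            "intercept": self.intercept,
            "seed": self.seed,
        }


def generate(config: SimConfig) -> tuple[Dataset, tuple]:
    """Generate one dataset from the config; returns (Dataset, truth set).

    Deterministic per seed.  The truth set is the planted informative
    index set (empty under the null scenario).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.predictor_prob_range
    probs = rng.uniform(lo, hi, size=config.n_variables)
    X = (rng.random((config.n_samples, config.n_variables)) < probs).astype(float)

    eta = np.full(config.n_samples, config.intercept, dtype=float)
    for j, beta in zip(config.informative_indices, config.effect_sizes):
        eta += beta * X[:, j]
    p = expit(eta)
    y = (rng.random(config.n_samples) < p).astype(int)

    names = tuple(f"X{j + 1}" for j in range(config.n_variables))
    refs = tuple("0" for _ in names)
    ds = Dataset(X=X, Y=y, column_names=names, reference_levels=refs)
    return ds, tuple(sorted(config.informative_indices))


def paper_scale_fixture(
    seed: int,
    planted: bool = False,
    n_informative: int = 5,
    effect_size: float = 1.0,
) -> tuple[Dataset, tuple, np.ndarray, np.ndarray]:
    """A 5000 x 100 dataset with a 70:30 stratified train/test split.

    Returns (dataset, truth, train_rows, test_rows).  With
    ``planted=True`` the first ``n_informative`` columns carry a
    log-odds effect of ``effect_size``; otherwise the response is pure
    noise.
    """
    if planted:
        idx = tuple(range(n_informative))
        betas = tuple(effect_size for _ in idx)
        # centre the intercept so classes stay roughly balanced
        intercept = -effect_size * n_informative * 0.5
    else:
        idx, betas, intercept = (), (), 0.0
    config = SimConfig(
        n_samples=5000,
        n_variables=100,
        informative_indices=idx,
        effect_sizes=betas,
        intercept=intercept,
        seed=seed,
    )
    ds, truth = generate(config)
    train, test = stratified_split(ds.Y, test_fraction=0.3, seed=seed)
    return ds, truth, train, test


def recovery_fixture(seed: int) -> tuple[Dataset, tuple]:
    """The planted-signal recovery scenario: n=2000, v=50, five unit effects.

    Five of fifty Bernoulli columns carry a log-odds effect of 1.0; the
    intercept is centred at -2.5 so the two classes stay roughly
    balanced.  Returns (dataset, truth set).
    """
    config = SimConfig(
        n_samples=2000,
        n_variables=50,
        informative_indices=tuple(range(5)),
        effect_sizes=(1.0,) * 5,
        intercept=-2.5,
        seed=seed,
    )
    return generate(config)


def stratified_split(
    y: np.ndarray, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified row split; returns (train_rows, test_rows)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    test_parts = []
    for cls in np.unique(y):
        rows = np.nonzero(y == cls)[0]
        n_test = int(round(test_fraction * rows.size))
        test_parts.append(rng.permutation(rows)[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def write_fixture(dataset: Dataset, config: SimConfig, path: str | Path) -> None:
    """Write a generated dataset as CSV with its config as a JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(dataset.X.astype(int), columns=list(dataset.column_names))
    frame.insert(0, "Y", dataset.Y)
    frame.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(config.as_dict(), indent=2))
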