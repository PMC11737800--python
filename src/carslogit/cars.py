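"""The CARS selection engine.

Competitive adaptive re-weighted sampling couples four ingredients:

1. *Monte-Carlo sampling* — each of N runs fits a logistic model on a
   random row subsample of the data using the currently surviving
   variables.
2. *Coefficient weights* — each surviving variable i gets the normalized
   weight h_i = |c_i| / sum|c_i| from that fit.
3. *Forced elimination* — an exponentially decreasing function (EDF)
   fixes the fraction q_i = z e^{-t i} of variables kept at run i, with
   z and t pinned by q_1 = 1 (all v variables enter run 1) and
   q_N = 2/v (two variables remain at run N); the lowest-weight
   variables are removed down to that count.
4. *Adaptive re-weighted sampling (ARS)* — the remaining variables are
   resampled with replacement with probability proportional to weight;
   the distinct drawn set is the competitive survivor pool.

Every run's survivor set is scored by 10-fold cross-validated deviance
on the full data; the subset with the lowest score wins ("survival of
the fittest") and is refit on all rows, optionally pruned by Wald
significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import Dataset, FittedLogistic, ModelAssessment
from .logistic_core import (
    OddsRatioRow,
    assess_model,
    cv_deviance,
    fit_logistic,
    odds_ratio_table,
)

__all__ = [
    "EDFSchedule",
    "RunRecord",
    "SelectionResult",
    "edf_schedule",
    "normalize_weights",
    "edf_eliminate",
    "ars_sample",
    "run_cars",
]


@dataclass(frozen=True)
class EDFSchedule:
    """The exponentially decreasing keep-ratio schedule over N runs.

    q_i = z e^{-t i} with z = (v/2)^{1/(N-1)} and t = ln(v/2)/(N-1), so
    that q_1 = 1 and q_N = 2/v exactly.  keep_count_i = max(2,
    round(q_i * v)) with round-half-up.
    """

    v: int
    N: int
    z: float
    t: float
    keep_ratio: tuple
    keep_count: tuple


@dataclass(frozen=True)
class RunRecord:
    """One Monte-Carlo run of the CARS loop."""

    run_index: int
    sampled_rows: tuple
    surviving_variables: tuple
    weights: tuple
    cv_score: float
    model_size: int
    failed: bool = False
    used_ridge_fallback: bool = False

    def as_dict(self) -> dict:
        return {
            "run_index": self.run_index,
            "surviving_variables": list(self.surviving_variables),
            "weights": list(self.weights),
            "cv_score": None if self.failed else self.cv_score,
            "model_size": self.model_size,
            "failed": self.failed,
            "used_ridge_fallback": self.used_ridge_fallback,
        }


@dataclass(frozen=True)
class SelectionResult:
    """The outcome of a selection procedure: winning subset plus report."""

    selected_variables: tuple
    best_run: int
    final_model: FittedLogistic
    assessment: ModelAssessment
    odds_ratios: tuple
    trace: tuple
    seed: int
    method: str = "cars"
    config: dict = field(default_factory=dict)

    def selected_names(self, dataset: Dataset) -> list[str]:
        return [dataset.column_names[j] for j in self.selected_variables]

    def as_dict(self, dataset: Dataset | None = None) -> dict:
        names = None
        if dataset is not None:
            names = self.selected_names(dataset)
        return {
            "method": self.method,
            "seed": self.seed,
            "config": self.config,
            "selected_variables": list(self.selected_variables),
            "selected_names": names,
            "best_run": self.best_run,
            "final_model": {
                "intercept": self.final_model.intercept,
                "coefficients": list(self.final_model.coefficients),
                "included_variables": list(self.final_model.included_variables),
                "log_likelihood": self.final_model.log_likelihood,
                "null_log_likelihood": self.final_model.null_log_likelihood,
                "n_obs": self.final_model.n_obs,
                "converged": self.final_model.converged,
                "used_ridge_fallback": self.final_model.used_ridge_fallback,
            },
            "assessment": self.assessment.as_dict(),
            "odds_ratios": [
                {
                    "variable": r.variable,
                    "reference_group": r.reference_group,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "wald_p": None if not np.isfinite(r.wald_p) else r.wald_p,
                    "has_ci": r.has_ci,
                }
                for r in self.odds_ratios
            ],
            "trace": [t.as_dict() if isinstance(t, RunRecord) else t for t in self.trace],
        }


def edf_schedule(v: int, N: int) -> EDFSchedule:
    """Build the EDF keep schedule for v variables over N sampling runs.

    Raises ``ValueError`` for v < 3 (the q_1 = 1 and q_N = 2/v endpoint
    conditions coincide or invert) or N < 2.
    """
    if v < 3:
        raise ValueError(f"v must be >= 3, got {v}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    z = (v / 2.0) ** (1.0 / (N - 1))
    t = math.log(v / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    q = z * np.exp(-t * i)
    counts = np.maximum(2, np.floor(q * v + 0.5).astype(int))  # round half up
    counts[0] = v
    counts[-1] = 2
    return EDFSchedule(
        v=v, N=N, z=z, t=t, keep_ratio=tuple(q.tolist()), keep_count=tuple(counts.tolist())
    )


def normalize_weights(coefficients: np.ndarray) -> np.ndarray:
    """Normalized importance weights h_i = |c_i| / sum_j |c_j|."""
    c = np.abs(np.asarray(coefficients, dtype=float))
    total = c.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate weights: all coefficients are zero")
    return c / total


def edf_eliminate(weights: np.ndarray, keep_count: int) -> np.ndarray:
    """Positions of the ``keep_count`` largest weights (forced elimination).

    Ties are broken in favour of the lower index; if there are no more
    than ``keep_count`` weights, all positions are returned.
    """
    if keep_count < 2:
        raise ValueError("keep_count must be >= 2")
    w = np.asarray(weights, dtype=float)
    if w.size <= keep_count:
        return np.arange(w.size)
    order = np.argsort(-w, kind="stable")  # stable => lower index wins ties
    return np.sort(order[:keep_count])


def ars_sample(
    weights: np.ndarray,
    n_draws: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Adaptive re-weighted sampling: weight-proportional draws with replacement.

    Draws ``n_draws`` positions with probability proportional to weight
    and returns the sorted distinct set (at least 1, at most n_draws
    positions).  Zero-weight positions can never be drawn.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    drawn = rng.choice(w.size, size=n_draws, replace=True, p=p)
    return np.unique(drawn)


def run_cars(
    dataset: Dataset,
    N: int = 50,
    k_folds: int = 10,
    row_fraction: float = 0.8,
    weight_threshold: float = 0.05,
    threshold_mode: str = "pvalue",
    seed: int = 0,
    fold_mode: str = "stratified",
    cv_loss: str = "deviance",
    ridge_fallback: float = 1e-6,
) -> SelectionResult:
    """Run the full CARS-Logistic selection loop.

    Each of the N Monte-Carlo runs (1) samples ``floor(row_fraction*s)``
    rows without replacement, (2) fits a logistic model on the current
    survivors, (3) computes normalized coefficient weights, (4) forces
    the pool down to the EDF keep count, (5) ARS-resamples that many
    draws from the survivors, and (6) scores the resulting distinct set
    by k-fold cross-validated deviance on the full data.  The minimum
    cross-validation score wins and is refit on all rows.

    ``threshold_mode='pvalue'`` (default) prunes the winning set to the
    variables with final-model Wald p below ``weight_threshold`` before
    the final refit; ``'weight'`` instead applies the threshold per run
    as a normalized-weight cutoff and performs no final prune.

    The master seed spawns one substream per run, so earlier runs are
    unchanged when N grows.  The whole procedure is a pure function of
    (dataset, config, seed).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 < row_fraction <= 1:
        raise ValueError("row_fraction must be in (0, 1]")
    if threshold_mode not in {"pvalue", "weight"}:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    v = dataset.n_variables
    s = dataset.n_samples
    schedule = edf_schedule(v, N)
    n_rows = int(math.floor(row_fraction * s))

    master = np.random.SeedSequence(int(seed))
    streams = master.spawn(N)

    survivors = np.arange(v)
    trace: list[RunRecord] = []
    config = {
        "N": N,
        "k_folds": k_folds,
        "row_fraction": row_fraction,
        "weight_threshold": weight_threshold,
        "threshold_mode": threshold_mode,
        "fold_mode": fold_mode,
        "cv_loss": cv_loss,
    }

    for i in range(1, N + 1):
        rng = np.random.default_rng(streams[i - 1])
        rows = np.sort(rng.choice(s, size=n_rows, replace=False))
        cv_seed = int(rng.integers(2**31))
        keep = schedule.keep_count[i - 1]
        failed_record = RunRecord(
            run_index=i,
            sampled_rows=tuple(rows.tolist()),
            surviving_variables=tuple(survivors.tolist()),
            weights=(),
            cv_score=float("inf"),
            model_size=len(survivors),
            failed=True,
        )
        try:
            sub = dataset.subset_rows(rows)
            fit = fit_logistic(sub, survivors, ridge_fallback=ridge_fallback)
            weights = normalize_weights(fit.coefficients)
        except ValueError:
            trace.append(failed_record)
            continue

        pool = survivors
        if threshold_mode == "weight":
            # per-run weight cutoff; always retain at least the top two
            above = weights >= weight_threshold
            if above.sum() < 2:
                above = np.zeros_like(above)
                above[np.argsort(-weights, kind="stable")[:2]] = True
            pool = pool[above]
            weights = weights[above] / weights[above].sum()

        keep_pos = edf_eliminate(weights, keep)
        pool = pool[keep_pos]
        w_pool = weights[keep_pos] / weights[keep_pos].sum()

        drawn_pos = ars_sample(w_pool, n_draws=keep, rng=rng)
        new_survivors = pool[drawn_pos]
        w_new = w_pool[drawn_pos] / w_pool[drawn_pos].sum()

        try:
            score = cv_deviance(
                dataset,
                new_survivors,
                k_folds=k_folds,
                seed=cv_seed,
                fold_mode=fold_mode,
                loss=cv_loss,
                ridge_fallback=ridge_fallback,
            )
        except ValueError:
            trace.append(failed_record)
            continue

        survivors = new_survivors
        trace.append(
            RunRecord(
                run_index=i,
                sampled_rows=tuple(rows.tolist()),
                surviving_variables=tuple(new_survivors.tolist()),
                weights=tuple(w_new.tolist()),
                cv_score=float(score),
                model_size=len(new_survivors),
                failed=False,
                used_ridge_fallback=fit.used_ridge_fallback,
            )
        )

    ok = [r for r in trace if not r.failed]
    if not ok:
        raise ValueError("all CARS runs failed; cannot select a subset")
    best = min(ok, key=lambda r: (r.cv_score, r.run_index))
    selected = list(best.surviving_variables)

    final = fit_logistic(dataset, selected, ridge_fallback=ridge_fallback)
    if threshold_mode == "pvalue":
        ors = odds_ratio_table(final, dataset)
        retained = [
            col
            for col, row in zip(final.included_variables, ors)
            if row.has_ci and row.wald_p < weight_threshold
        ]
        if retained and len(retained) < len(selected):
            selected = retained
            final = fit_logistic(dataset, selected, ridge_fallback=ridge_fallback)

    return SelectionResult(
        selected_variables=tuple(selected),
        best_run=best.run_index,
        final_model=final,
        assessment=assess_model(final),
        odds_ratios=tuple(odds_ratio_table(final, dataset)),
        trace=tuple(trace),
        seed=int(seed),
        method="cars",
        config=config,
    )
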