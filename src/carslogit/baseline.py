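"""Forward-selection logistic regression, the comparison baseline.

Greedy stepwise search from the intercept-only model: under the AIC
criterion the column giving the largest AIC decrease enters at each
step; under the p-value criterion the column with the smallest Wald
p-value enters while it stays below ``p_enter``.
"""

from __future__ import annotations

import numpy as np

from .data_model import Dataset
from .cars import SelectionResult
from .logistic_core import assess_model, fit_logistic, odds_ratio_table

__all__ = ["forward_select"]


def forward_select(
    dataset: Dataset,
    criterion: str = "aic",
    p_enter: float = 0.05,
    max_steps: int | None = None,
    ridge_fallback: float = 1e-6,
) -> SelectionResult:
    """Greedy forward selection of predictor columns for a logistic model.

    Returns a :class:`SelectionResult` whose trace records, per step, the
    entering column and the criterion value, so that the AIC path (which
    must be strictly decreasing under ``criterion='aic'``) can be
    inspected.  Candidate fits that fail are skipped; if none converge
    at a step, selection stops and the event is recorded in the trace.
    """
    if criterion not in {"aic", "pvalue"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    v = dataset.n_variables
    if max_steps is None:
        max_steps = v

    current: list[int] = []
    null_fit = fit_logistic(dataset, [], ridge_fallback=ridge_fallback)
    current_aic = assess_model(null_fit).aic
    trace: list[dict] = [{"step": 0, "entered": None, "aic": current_aic}]

    for step in range(1, max_steps + 1):
        remaining = [j for j in range(v) if j not in current]
        if not remaining:
            break
        best = None  # (sort key, column, fit, aic, p)
        any_converged = False
        for j in remaining:
            try:
                fit = fit_logistic(dataset, current + [j], ridge_fallback=ridge_fallback)
            except ValueError:
                continue
            any_converged = True
            aic = assess_model(fit).aic
            if criterion == "aic":
                key = (aic, j)
            else:
                ors = odds_ratio_table(fit, dataset)
                p = ors[-1].wald_p if ors[-1].has_ci else np.inf
                key = (p, j)
            if best is None or key < best[0]:
                ors = odds_ratio_table(fit, dataset)
                p_new = ors[-1].wald_p if ors[-1].has_ci else np.inf
                best = (key, j, fit, aic, p_new)
        if not any_converged:
            trace.append({"step": step, "entered": None, "warning": "no candidate fit converged"})
            break
        if best is None:
            break
        _, j, fit, aic, p_new = best
        if criterion == "aic" and aic >= current_aic:
            break
        if criterion == "pvalue" and not p_new < p_enter:
            break
        current.append(j)
        current_aic = aic
        trace.append(
            {
                "step": step,
                "entered": int(j),
                "entered_name": dataset.column_names[j],
                "aic": float(aic),
                "wald_p": float(p_new) if np.isfinite(p_new) else None,
            }
        )

    final = fit_logistic(dataset, current, ridge_fallback=ridge_fallback)
    return SelectionResult(
        selected_variables=tuple(current),
        best_run=len(current),
        final_model=final,
        assessment=assess_model(final),
        odds_ratios=tuple(odds_ratio_table(final, dataset)),
        trace=tuple(trace),
        seed=0,
        method="forward",
        config={"criterion": criterion, "p_enter": p_enter, "max_steps": max_steps},
    )
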