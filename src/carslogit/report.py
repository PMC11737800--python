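"""The CARS-vs-forward-selection comparison harness and serialization.

Both selection arms receive byte-identical preprocessed input.  By
default the comparison selects variables on a stratified 70% training
split and computes the five assessment criteria from held-out
log-likelihood on the remaining 30%, so that the criteria reward
generalisation rather than in-sample fit; ``test_fraction=0`` assesses
in-sample instead.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .baseline import forward_select
from .cars import SelectionResult, run_cars
from .data_model import Dataset, FittedLogistic, ModelAssessment
from .logistic_core import assess_model
from .preprocess import PreprocessReport, preprocess_pipeline
from .synthetic import stratified_split

__all__ = [
    "ComparisonReport",
    "compare_models",
    "overlap_percent",
    "holdout_assessment",
    "write_results_json",
    "write_summary_tsv",
    "write_comparison_tsv",
]

_PCLIP = 1e-12


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side CARS and forward-selection results on one dataset."""

    cars: SelectionResult
    forward: SelectionResult
    cars_assessment: ModelAssessment
    forward_assessment: ModelAssessment
    overlap_percent: float
    seed: int
    test_fraction: float
    input_sha256: str
    preprocess: PreprocessReport | None = None
    config: dict = field(default_factory=dict)

    def as_dict(self, dataset: Dataset | None = None) -> dict:
        return {
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "input_sha256": self.input_sha256,
            "overlap_percent": self.overlap_percent,
            "overlap_convention": "jaccard: 100*|a&b|/|a|b|",
            "config": self.config,
            "cars": self.cars.as_dict(dataset),
            "forward": self.forward.as_dict(dataset),
            "cars_assessment": self.cars_assessment.as_dict(),
            "forward_assessment": self.forward_assessment.as_dict(),
            "preprocess": self.preprocess.as_dict() if self.preprocess else None,
        }

    def metric_rows(self) -> list[dict]:
        """Tidy (metric, method, value) rows for the five criteria."""
        rows = []
        for method, a in (("cars", self.cars_assessment), ("forward", self.forward_assessment)):
            for metric, value in a.as_dict().items():
                rows.append({"metric": metric, "method": method, "value": value})
        return rows


def overlap_percent(a, b) -> float:
    """Subset overlap as a Jaccard percentage: 100*|a&b| / |a|b|.

    Defined as 0 when both sets are empty.
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 100.0 * len(a & b) / len(union)


def dataset_sha256(dataset: Dataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.X).tobytes())
    h.update(np.ascontiguousarray(dataset.Y).tobytes())
    h.update("\x1f".join(dataset.column_names).encode())
    return h.hexdigest()


def holdout_assessment(
    model: FittedLogistic, dataset: Dataset, test_rows: np.ndarray, train_rows: np.ndarray
) -> ModelAssessment:
    """Five criteria computed from held-out log-likelihood.

    The model's coefficients (fit on the training rows) are evaluated on
    the test rows; the null log-likelihood uses the training event rate.
    Parameter count is unchanged.
    """
    y_test = np.asarray(dataset.Y)[test_rows].astype(float)
    p = model.predict_proba(dataset.X[test_rows], model.included_variables)
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    ll = float(np.sum(y_test * np.log(p) + (1.0 - y_test) * np.log(1.0 - p)))
    p0 = float(np.asarray(dataset.Y)[train_rows].mean())
    p0 = min(max(p0, _PCLIP), 1.0 - _PCLIP)
    ll0 = float(np.sum(y_test * np.log(p0) + (1.0 - y_test) * np.log(1.0 - p0)))
    proxy = replace(
        model,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        n_obs=int(len(test_rows)),
    )
    return assess_model(proxy)


def compare_models(
    dataset: Dataset,
    seed: int = 0,
    test_fraction: float = 0.3,
    run_preprocess: bool = True,
    cars_options: dict | None = None,
    forward_options: dict | None = None,
) -> ComparisonReport:
    """Run CARS and forward selection on identical inputs and compare.

    The dataset is preprocessed once (NZV -> outliers -> correlation,
    unless ``run_preprocess=False``); both arms then select on the same
    training rows.  With ``test_fraction > 0`` the assessment criteria
    are computed on the held-out split; selected-variable indices in the
    report refer to the preprocessed dataset's columns.
    """
    cars_options = dict(cars_options or {})
    forward_options = dict(forward_options or {})

    pre_report = None
    if run_preprocess:
        dataset, pre_report = preprocess_pipeline(dataset)
    digest = dataset_sha256(dataset)

    if test_fraction > 0:
        train, test = stratified_split(dataset.Y, test_fraction=test_fraction, seed=seed)
        train_ds = dataset.subset_rows(train)
    else:
        train = np.arange(dataset.n_samples)
        test = train
        train_ds = dataset

    cars_res = run_cars(train_ds, seed=seed, **cars_options)
    fs_res = forward_select(train_ds, **forward_options)

    if test_fraction > 0:
        cars_assessment = holdout_assessment(cars_res.final_model, dataset, test, train)
        fs_assessment = holdout_assessment(fs_res.final_model, dataset, test, train)
    else:
        cars_assessment = cars_res.assessment
        fs_assessment = fs_res.assessment

    return ComparisonReport(
        cars=cars_res,
        forward=fs_res,
        cars_assessment=cars_assessment,
        forward_assessment=fs_assessment,
        overlap_percent=overlap_percent(cars_res.selected_variables, fs_res.selected_variables),
        seed=int(seed),
        test_fraction=test_fraction,
        input_sha256=digest,
        preprocess=pre_report,
        config={
            "cars_options": cars_options,
            "forward_options": forward_options,
            "run_preprocess": run_preprocess,
        },
    )


def write_results_json(obj, path: str | Path, dataset: Dataset | None = None) -> None:
    """Serialize a SelectionResult or ComparisonReport to JSON."""
    payload = obj.as_dict(dataset)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_summary_tsv(result: SelectionResult, dataset: Dataset, path: str | Path) -> None:
    """Odds-ratio summary table, one row per selected variable."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["variable", "reference_group", "OR", "CI_low", "CI_high", "p"])
        for row in result.odds_ratios:
            writer.writerow(
                [
                    row.variable,
                    row.reference_group,
                    f"{row.odds_ratio:.6g}",
                    f"{row.ci_low:.6g}" if row.has_ci else "NA",
                    f"{row.ci_high:.6g}" if row.has_ci else "NA",
                    f"{row.wald_p:.6g}" if row.has_ci else "NA",
                ]
            )


def write_comparison_tsv(report: ComparisonReport, path: str | Path) -> None:
    """Tidy (metric, method, value) table of the five criteria per arm."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["metric", "method", "value"])
        for row in report.metric_rows():
            writer.writerow([row["metric"], row["method"], f"{row['value']:.10g}"])
        writer.writerow(["overlap_percent", "both", f"{report.overlap_percent:.10g}"])
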