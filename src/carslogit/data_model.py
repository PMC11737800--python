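"""Typed containers for datasets and fitted models, table I/O and validation.

A :class:`Dataset` holds an ``s x v`` matrix of numeric-coded predictors
and a binary response vector.  Categorical text columns are coded by
sorted-level integer assignment; categoricals with more than two levels
are expanded to reference-coded indicator columns so that every column
carries exactly one regression coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "FittedLogistic",
    "ModelAssessment",
    "Violation",
    "load_table",
    "validate",
]


@dataclass(frozen=True)
class Dataset:
    """A rectangular sample-by-variable table with a binary response.

    Parameters
    ----------
    X : ndarray of shape (s, v)
        Numeric-coded predictors; rows are samples, columns variables.
    Y : ndarray of shape (s,)
        Binary response with values in {0, 1}.
    column_names : tuple of str
        One unique label per predictor column.
    reference_levels : tuple of str or None
        Optional reference-group label per column, used when reporting
        odds ratios for coded categorical predictors.
    """

    X: np.ndarray
    Y: np.ndarray
    column_names: tuple
    reference_levels: tuple | None = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "column_names", tuple(self.column_names))
        if self.reference_levels is not None:
            object.__setattr__(self, "reference_levels", tuple(self.reference_levels))
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if Y.shape != (X.shape[0],):
            raise ValueError("Y length must equal the number of rows of X")
        if len(self.column_names) != X.shape[1]:
            raise ValueError("column_names length must equal the number of columns of X")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, rows: np.ndarray) -> "Dataset":
        """Return a new Dataset restricted to the given row indices."""
        return replace(self, X=self.X[rows], Y=self.Y[rows])

    def subset_columns(self, cols: Sequence[int]) -> "Dataset":
        """Return a new Dataset restricted to the given column indices."""
        cols = list(cols)
        refs = None
        if self.reference_levels is not None:
            refs = tuple(self.reference_levels[c] for c in cols)
        return Dataset(
            X=self.X[:, cols],
            Y=self.Y,
            column_names=tuple(self.column_names[c] for c in cols),
            reference_levels=refs,
        )


@dataclass(frozen=True)
class FittedLogistic:
    """A maximum-likelihood (or ridge-stabilised) logistic regression fit."""

    intercept: float
    coefficients: np.ndarray
    included_variables: tuple
    log_likelihood: float
    null_log_likelihood: float
    n_obs: int
    converged: bool
    std_errors: np.ndarray
    used_ridge_fallback: bool = False

    @property
    def n_params(self) -> int:
        """Number of estimated parameters, intercept included."""
        return 1 + len(self.coefficients)

    def predict_proba(self, X: np.ndarray, columns: Sequence[int] | None = None) -> np.ndarray:
        """Fitted event probability for each row of ``X``.

        ``columns`` maps the fit's coefficient order onto columns of X;
        defaults to ``included_variables``.
        """
        from scipy.special import expit

        cols = list(self.included_variables if columns is None else columns)
        eta = np.full(X.shape[0], self.intercept, dtype=float)
        if cols:
            eta += X[:, cols] @ self.coefficients
        return expit(eta)


@dataclass(frozen=True)
class ModelAssessment:
    """The five model-assessment criteria for one fitted logistic model."""

    aic: float
    bic: float
    mcfadden_r2: float
    mcfadden_adj_r2: float
    cox_snell_r2: float

    def as_dict(self) -> dict:
        return {
            "aic": self.aic,
            "bic": self.bic,
            "mcfadden_r2": self.mcfadden_r2,
            "mcfadden_adj_r2": self.mcfadden_adj_r2,
            "cox_snell_r2": self.cox_snell_r2,
        }


@dataclass(frozen=True)
class Violation:
    """One validated-invariant failure, locatable to a column and/or row."""

    invariant: str
    message: str
    column: str | None = None
    row: int | None = None

    def as_dict(self) -> dict:
        return {
            "invariant": self.invariant,
            "column": self.column,
            "row": self.row,
            "message": self.message,
        }


def _code_binary_response(series: pd.Series, name: str) -> tuple[np.ndarray, str]:
    levels = sorted(series.dropna().unique(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"response not binary: column {name!r} has {len(levels)} level(s) {levels!r}"
        )
    coded = (series == levels[1]).astype(int).to_numpy()
    return coded, str(levels[0])


def load_table(
    path: str | Path,
    response: str,
    delimiter: str | None = None,
) -> Dataset:
    """Read a delimited table and return a coded, validated :class:`Dataset`.

    The delimiter is inferred from the extension (``.tsv``/``.tab`` =>
    tab, otherwise comma) unless given explicitly.  Text columns are
    integer-coded by sorted level; columns with more than two levels are
    expanded to reference-coded indicators named ``column=level``.  The
    first sorted level is the recorded reference level.

    Raises
    ------
    ValueError
        If the response column is absent or not two-level, the table is
        empty, or any cell is missing (reported with row and column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=delimiter)
    if frame.empty:
        raise ValueError("empty table")
    if response not in frame.columns:
        raise ValueError(f"missing response column {response!r}")

    missing = frame.isna()
    if missing.to_numpy().any():
        rows, cols = np.nonzero(missing.to_numpy())
        col = frame.columns[cols[0]]
        raise ValueError(
            f"missing value at row {int(rows[0])}, column {col!r} "
            f"({int(missing.to_numpy().sum())} missing cell(s) total)"
        )

    y, _ = _code_binary_response(frame[response], response)

    columns: list[np.ndarray] = []
    names: list[str] = []
    refs: list[str] = []
    for name in frame.columns:
        if name == response:
            continue
        series = frame[name]
        if pd.api.types.is_numeric_dtype(series):
            columns.append(series.to_numpy(dtype=float))
            names.append(str(name))
            refs.append("")
            continue
        levels = sorted(series.astype(str).unique())
        if len(levels) <= 1:
            # constant text column: coded as all-zero; NZV filter will drop it
            columns.append(np.zeros(len(series)))
            names.append(str(name))
            refs.append(levels[0] if levels else "")
        elif len(levels) == 2:
            columns.append((series.astype(str) == levels[1]).astype(float).to_numpy())
            names.append(str(name))
            refs.append(levels[0])
        else:
            for level in levels[1:]:
                columns.append((series.astype(str) == level).astype(float).to_numpy())
                names.append(f"{name}={level}")
                refs.append(levels[0])

    if not columns:
        raise ValueError("table has no predictor columns")
    X = np.column_stack(columns)
    return Dataset(X=X, Y=y, column_names=tuple(names), reference_levels=tuple(refs))


def validate(dataset: Dataset) -> list[Violation]:
    """Check every Dataset invariant; return one Violation per failure.

    An empty list means the dataset satisfies all invariants: a two-class
    {0,1} response, a complete predictor matrix with at least 10 rows and
    2 columns, and unique column names.
    """
    out: list[Violation] = []
    y = np.asarray(dataset.Y)
    vals = set(np.unique(y).tolist())
    if not vals <= {0, 1}:
        out.append(
            Violation("response-binary", f"response contains values other than 0/1: {sorted(vals)}")
        )
    elif len(vals) < 2:
        out.append(Violation("response-single-class", f"response has a single class ({vals})"))

    bad = np.argwhere(~np.isfinite(dataset.X))
    if bad.size:
        r, c = bad[0]
        out.append(
            Violation(
                "no-missing",
                f"{bad.shape[0]} non-finite value(s) in X; first at row {int(r)}",
                column=dataset.column_names[int(c)],
                row=int(r),
            )
        )
    if dataset.n_samples < 10:
        out.append(Violation("min-samples", f"s = {dataset.n_samples} < 10"))
    if dataset.n_variables < 2:
        out.append(Violation("min-variables", f"v = {dataset.n_variables} < 2"))

    seen: dict[str, int] = {}
    for i, name in enumerate(dataset.column_names):
        if name in seen:
            out.append(
                Violation(
                    "unique-column-names",
                    f"column name {name!r} duplicated (positions {seen[name]} and {i})",
                    column=name,
                )
            )
        else:
            seen[name] = i
    return out
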