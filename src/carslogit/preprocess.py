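"""Logistic-regression assumption pipeline.

Near-zero-variance filtering, outlier removal via standardized Pearson
residuals from a full-model fit, pairwise-correlation filtering, and the
binned-residual independence diagnostic.  The pipeline order is
NZV -> outliers -> correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import Dataset, FittedLogistic
from .logistic_core import fit_logistic

__all__ = [
    "PreprocessReport",
    "BinnedResidualDiagnostic",
    "near_zero_variance_filter",
    "remove_outliers",
    "correlation_filter",
    "binned_residuals",
    "preprocess_pipeline",
]


@dataclass
class PreprocessReport:
    """What each filter dropped and what survived."""

    dropped_nzv: list = field(default_factory=list)
    dropped_outlier_rows: list = field(default_factory=list)
    dropped_correlated: list = field(default_factory=list)  # (dropped, partner) pairs
    surviving_columns: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "dropped_nzv": list(self.dropped_nzv),
            "dropped_outlier_rows": [int(r) for r in self.dropped_outlier_rows],
            "dropped_correlated": [
                {"dropped": d, "partner": p} for d, p in self.dropped_correlated
            ],
            "surviving_columns": list(self.surviving_columns),
        }


@dataclass(frozen=True)
class BinnedResidualDiagnostic:
    """Per-bin mean residual vs mean fitted probability, with a normal band.

    ``bins`` holds (mean fitted probability, mean raw residual, band
    half-width) triples; ``fraction_in_band`` is the share of bins whose
    mean residual lies inside its band.
    """

    bins: tuple
    fraction_in_band: float

    def to_rows(self) -> list[dict]:
        return [
            {"bin": i + 1, "mean_p": p, "mean_resid": r, "half_width": w}
            for i, (p, r, w) in enumerate(self.bins)
        ]


def near_zero_variance_filter(
    dataset: Dataset,
    freq_ratio_cut: float = 19.0,
    unique_pct_cut: float = 10.0,
) -> tuple[Dataset, PreprocessReport]:
    """Drop near-constant predictor columns.

    A column is near-zero-variance when its most-common/second-most-common
    frequency ratio exceeds ``freq_ratio_cut`` (default 19, i.e. 95:5) AND
    its distinct-value percentage is below ``unique_pct_cut``.  Constant
    columns are always dropped.
    """
    s = dataset.n_samples
    keep, dropped = [], []
    for j, name in enumerate(dataset.column_names):
        col = dataset.X[:, j]
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 1:
            dropped.append(name)
            continue
        top = np.sort(counts)[::-1]
        ratio = top[0] / top[1]
        unique_pct = 100.0 * counts.size / s
        if ratio > freq_ratio_cut and unique_pct < unique_pct_cut:
            dropped.append(name)
        else:
            keep.append(j)
    if not keep:
        raise ValueError("no predictors survive NZV filtering")
    report = PreprocessReport(
        dropped_nzv=dropped,
        surviving_columns=[dataset.column_names[j] for j in keep],
    )
    return dataset.subset_columns(keep), report


def _independent_columns(X: np.ndarray) -> list[int]:
    """A maximal linearly independent predictor subset (after an intercept).

    Fitted probabilities — and therefore residuals — are invariant to the
    basis chosen for the design's column space, so the full-model outlier
    fit can safely drop exactly aliased columns (e.g. duplicates that the
    correlation filter has not yet seen).
    """
    from scipy.linalg import qr

    Xd = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank == Xd.shape[1]:
        return list(range(X.shape[1]))
    _, _, piv = qr(Xd, mode="economic", pivoting=True)
    kept = {int(i) - 1 for i in piv[:rank] if i > 0}
    return sorted(kept)


def remove_outliers(
    dataset: Dataset,
    resid_cut: float = 3.0,
    model: FittedLogistic | None = None,
) -> tuple[Dataset, PreprocessReport]:
    """Drop rows that are outliers under the full-model logistic fit.

    A row is an outlier when its Pearson residual (y - p)/sqrt(p(1-p))
    from the full fit exceeds ``resid_cut`` in absolute value.  Aborts if
    more than 20% of rows would drop — that pattern suggests model
    misspecification rather than stray observations.
    """
    if model is None:
        model = fit_logistic(dataset, _independent_columns(dataset.X))
    p = model.predict_proba(dataset.X)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    resid = (dataset.Y - p) / np.sqrt(p * (1.0 - p))
    out = np.abs(resid) > resid_cut
    n_out = int(out.sum())
    if n_out > 0.2 * dataset.n_samples:
        raise ValueError(
            f"{n_out}/{dataset.n_samples} rows exceed |residual| > {resid_cut}; "
            "this suggests misspecification, not outliers"
        )
    report = PreprocessReport(
        dropped_outlier_rows=np.nonzero(out)[0].tolist(),
        surviving_columns=list(dataset.column_names),
    )
    return dataset.subset_rows(~out), report


def correlation_filter(
    dataset: Dataset, cutoff: float = 0.7
) -> tuple[Dataset, PreprocessReport]:
    """Iteratively remove one member of each highly correlated pair.

    While any absolute pairwise Pearson correlation exceeds ``cutoff``,
    the member of the worst pair with the larger mean absolute
    correlation against all other surviving columns is dropped.  Ties
    keep the lower column index.  Deterministic given column order.
    """
    if dataset.n_variables < 2:
        raise ValueError("correlation filter needs at least 2 predictor columns")
    names = dataset.column_names
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(dataset.X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)

    alive = list(range(dataset.n_variables))
    dropped_pairs = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= cutoff:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[a], alive[b]
        mean_i = sub[a].sum() / (len(alive) - 1)
        mean_j = sub[b].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            drop, partner = i, j
        elif mean_j > mean_i:
            drop, partner = j, i
        else:  # tie: keep the lower original column index
            drop, partner = max(i, j), min(i, j)
        dropped_pairs.append((names[drop], names[partner]))
        alive.remove(drop)

    report = PreprocessReport(
        dropped_correlated=dropped_pairs,
        surviving_columns=[names[j] for j in alive],
    )
    return dataset.subset_columns(alive), report


def binned_residuals(
    model: FittedLogistic,
    dataset: Dataset,
    n_bins: int | None = None,
    band_level: float = 0.90,
) -> BinnedResidualDiagnostic:
    """Binned-residual diagnostic for a binary-outcome fit.

    Rows are sorted by fitted probability and split into ``n_bins``
    near-equal bins (default floor(sqrt(s))).  Each bin reports the mean
    raw residual y - p and a two-sided normal band of half-width
    z * sd(residuals)/sqrt(bin size) at ``band_level``.
    """
    s = dataset.n_samples
    if n_bins is None:
        n_bins = int(math.floor(math.sqrt(s)))
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    p = model.predict_proba(dataset.X)
    resid = dataset.Y - p
    order = np.argsort(p, kind="stable")
    z = stats.norm.ppf(0.5 + band_level / 2.0)
    bins = []
    inside = 0
    for chunk in np.array_split(order, n_bins):
        if chunk.size < 2:
            raise ValueError("bin size < 2; reduce n_bins")
        r = resid[chunk]
        half = z * r.std(ddof=1) / math.sqrt(chunk.size)
        mean_r = float(r.mean())
        bins.append((float(p[chunk].mean()), mean_r, float(half)))
        if abs(mean_r) <= half:
            inside += 1
    return BinnedResidualDiagnostic(bins=tuple(bins), fraction_in_band=inside / n_bins)


def preprocess_pipeline(
    dataset: Dataset,
    freq_ratio_cut: float = 19.0,
    unique_pct_cut: float = 10.0,
    resid_cut: float = 3.0,
    corr_cutoff: float = 0.7,
) -> tuple[Dataset, PreprocessReport]:
    """NZV filter, then outlier removal, then correlation filter."""
    ds, rep_nzv = near_zero_variance_filter(dataset, freq_ratio_cut, unique_pct_cut)
    ds, rep_out = remove_outliers(ds, resid_cut)
    ds, rep_corr = correlation_filter(ds, corr_cutoff)
    report = PreprocessReport(
        dropped_nzv=rep_nzv.dropped_nzv,
        dropped_outlier_rows=rep_out.dropped_outlier_rows,
        dropped_correlated=rep_corr.dropped_correlated,
        surviving_columns=rep_corr.surviving_columns,
    )
    return ds, report
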