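"""Maximum-likelihood logistic regression with assessment and odds ratios.

The model engine every other module calls.  Fits go through statsmodels'
Newton solver; if separation or non-convergence is detected the fit is
repeated with a small L2 penalty (hand-written Newton-IRLS, since an
L2-penalised logistic fit with standard errors is not otherwise
available) and flagged accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .data_model import Dataset, FittedLogistic, ModelAssessment

__all__ = [
    "OddsRatioRow",
    "fit_logistic",
    "assess_model",
    "odds_ratio_table",
    "cv_deviance",
    "null_log_likelihood",
]

_PCLIP = 1e-12


@dataclass(frozen=True)
class OddsRatioRow:
    """One line of an odds-ratio report: OR = exp(coefficient), Wald CI/p."""

    variable: str
    reference_group: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    has_ci: bool = True


def null_log_likelihood(y: np.ndarray) -> float:
    """Intercept-only log-likelihood: n[p ln p + (1-p) ln(1-p)], p = mean(y)."""
    y = np.asarray(y)
    n = y.size
    k = int(y.sum())
    if k == 0 or k == n:
        raise ValueError("single-class response: null model is degenerate")
    p = k / n
    return k * np.log(p) + (n - k) * np.log(1.0 - p)


def _ridge_newton(
    X: np.ndarray, y: np.ndarray, alpha: float, max_iter: int = 200, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """L2-penalised logistic Newton-IRLS; intercept unpenalised.

    Returns (beta, std_errors from the penalised Hessian, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, 2.0 * alpha)
    pen[0] = 0.0  # leave the intercept unpenalised
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X.T * w) @ X + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = sorted(piv[rank:].tolist())
        labels = [names[i - 1] if i > 0 else "(intercept)" for i in aliased]
        raise ValueError(f"rank-deficient design; aliased columns: {labels}")


def fit_logistic(
    dataset: Dataset,
    columns: Sequence[int] | None = None,
    ridge_fallback: float = 1e-6,
) -> FittedLogistic:
    """MLE logistic fit of Y on the given predictor columns (plus intercept).

    ``columns`` may be empty for an intercept-only fit.  On separation or
    non-convergence the fit is repeated with an L2 penalty of strength
    ``ridge_fallback`` and ``used_ridge_fallback`` is set; ``converged``
    then reports the fallback solver's status.

    Raises
    ------
    ValueError
        If the response is single-class on these rows, the design is
        rank-deficient, or there are too few rows for the parameters.
    """
    cols = list(range(dataset.n_variables)) if columns is None else list(columns)
    y = np.asarray(dataset.Y, dtype=float)
    n = y.size
    if n <= len(cols) + 1:
        raise ValueError(f"too few rows (s={n}) for {len(cols)} predictors plus intercept")
    ll0 = null_log_likelihood(y)  # raises on single-class

    Xd = np.column_stack([np.ones(n)] + [dataset.X[:, c] for c in cols])
    names = [dataset.column_names[c] for c in cols]
    _check_rank(Xd, names)

    beta = se = None
    converged = fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=100, warn_convergence=False)
            beta = np.asarray(res.params, dtype=float)
            se = np.asarray(res.bse, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
            if not converged or not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
                beta = None
        except Exception:
            beta = None

    if beta is None:
        beta, se, converged = _ridge_newton(Xd, y, ridge_fallback)
        fallback = True

    p = expit(Xd @ beta)
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    return FittedLogistic(
        intercept=float(beta[0]),
        coefficients=np.asarray(beta[1:], dtype=float),
        included_variables=tuple(cols),
        log_likelihood=ll,
        null_log_likelihood=float(ll0),
        n_obs=n,
        converged=converged,
        std_errors=np.asarray(se[1:], dtype=float),
        used_ridge_fallback=fallback,
    )


def assess_model(model: FittedLogistic) -> ModelAssessment:
    """The five assessment criteria from the stored log-likelihoods.

    With k parameters (intercept included), log-likelihood l and null
    log-likelihood l0 on n observations:

        AIC              = 2k - 2l
        BIC              = k ln n - 2l
        McFadden R2      = 1 - l/l0
        adj. McFadden R2 = 1 - (l - k)/l0
        Cox & Snell R2   = 1 - exp(2(l0 - l)/n)
    """
    ll = model.log_likelihood
    ll0 = model.null_log_likelihood
    n = model.n_obs
    k = model.n_params
    if ll0 == 0.0:
        raise ValueError("null log-likelihood is zero: degenerate single-class response")
    return ModelAssessment(
        aic=2.0 * k - 2.0 * ll,
        bic=k * np.log(n) - 2.0 * ll,
        mcfadden_r2=1.0 - ll / ll0,
        mcfadden_adj_r2=1.0 - (ll - k) / ll0,
        cox_snell_r2=1.0 - np.exp(2.0 * (ll0 - ll) / n),
    )


def odds_ratio_table(
    model: FittedLogistic,
    dataset: Dataset,
    level: float = 0.95,
) -> list[OddsRatioRow]:
    """Per-variable odds ratios with Wald confidence intervals and p-values.

    OR = exp(c_i), CI = exp(c_i +/- z * SE_i) with z the two-sided normal
    quantile for ``level``.  Variables whose standard error is
    unavailable are reported with ``has_ci=False`` and a degenerate CI.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for j, col in enumerate(model.included_variables):
        c = float(model.coefficients[j])
        se = float(model.std_errors[j]) if j < len(model.std_errors) else np.nan
        o = float(np.exp(c))
        ref = ""
        if dataset.reference_levels is not None:
            ref = dataset.reference_levels[col]
        if np.isfinite(se) and se > 0:
            rows.append(
                OddsRatioRow(
                    variable=dataset.column_names[col],
                    reference_group=ref,
                    odds_ratio=o,
                    ci_low=float(np.exp(c - z * se)),
                    ci_high=float(np.exp(c + z * se)),
                    wald_p=float(2.0 * stats.norm.sf(abs(c / se))),
                    has_ci=True,
                )
            )
        else:
            rows.append(
                OddsRatioRow(
                    variable=dataset.column_names[col],
                    reference_group=ref,
                    odds_ratio=o,
                    ci_low=o,
                    ci_high=o,
                    wald_p=np.nan,
                    has_ci=False,
                )
            )
    return rows


def _interleaved_folds(y: np.ndarray, k_folds: int):
    """Round-robin fold assignment after sorting rows by response."""
    order = np.argsort(y, kind="stable")
    folds = [[] for _ in range(k_folds)]
    for pos, idx in enumerate(order):
        folds[pos % k_folds].append(idx)
    for test in folds:
        test = np.asarray(test)
        train = np.setdiff1d(np.arange(y.size), test)
        yield train, test


def cv_deviance(
    dataset: Dataset,
    columns: Sequence[int],
    k_folds: int = 10,
    seed: int = 0,
    fold_mode: str = "stratified",
    loss: str = "deviance",
    ridge_fallback: float = 1e-6,
) -> float:
    """Cross-validated prediction loss of the model with the given columns.

    With ``loss='deviance'`` (default) returns the mean held-out negative
    log-likelihood per observation across folds; ``loss='misclass'``
    returns the held-out misclassification rate at a 0.5 probability
    threshold.  ``fold_mode`` is ``'stratified'`` (seeded shuffled
    stratified k-fold) or ``'interleaved'`` (deterministic round-robin
    after sorting by response).  Deterministic given the seed.
    """
    y = np.asarray(dataset.Y)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n_minority = int(min((y == 0).sum(), (y == 1).sum()))
    if n_minority < k_folds:
        raise ValueError(
            f"minority class has {n_minority} rows < {k_folds} folds; use a smaller k"
        )
    if fold_mode == "stratified":
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(seed))
        split_iter = splitter.split(np.zeros(y.size), y)
    elif fold_mode == "interleaved":
        split_iter = _interleaved_folds(y, k_folds)
    else:
        raise ValueError(f"unknown fold_mode {fold_mode!r}")

    cols = list(columns)
    total = 0.0
    count = 0
    for train, test in split_iter:
        sub = dataset.subset_rows(train)
        model = fit_logistic(sub, cols, ridge_fallback=ridge_fallback)
        p = model.predict_proba(dataset.X[test], cols)
        yt = y[test].astype(float)
        if loss == "deviance":
            p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
            total += float(-np.sum(yt * np.log(p) + (1.0 - yt) * np.log(1.0 - p)))
        elif loss == "misclass":
            total += float(np.sum((p >= 0.5).astype(float) != yt))
        else:
            raise ValueError(f"unknown loss {loss!r}")
        count += test.size
    return total / count
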