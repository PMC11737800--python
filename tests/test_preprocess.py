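import numpy as np
import pytest
from scipy import stats

from carslogit import (
    SimConfig,
    binned_residuals,
    correlation_filter,
    fit_logistic,
    generate,
    near_zero_variance_filter,
    preprocess_pipeline,
    remove_outliers,
)
from carslogit.data_model import FittedLogistic

from conftest import make_dataset


def balanced(n, v, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, v)).astype(float)
    y = np.tile([0, 1], n // 2)
    return make_dataset(X, y)


class TestNearZeroVariance:
    def test_constant_column_dropped(self):
        ds = balanced(100, 2, seed=1)
        X = np.column_stack([ds.X, np.zeros(100)])
        ds = make_dataset(X, ds.Y)
        filtered, rep = near_zero_variance_filter(ds)
        assert "X3" in rep.dropped_nzv
        assert filtered.n_variables == 2

    def test_999_to_1_column_dropped_and_balanced_kept(self):
        rng = np.random.default_rng(2)
        rare = np.zeros(1000)
        rare[0] = 1.0
        bal = rng.integers(0, 2, 1000).astype(float)
        ds = make_dataset(np.column_stack([rare, bal]), np.tile([0, 1], 500))
        filtered, rep = near_zero_variance_filter(ds)
        assert rep.dropped_nzv == ["X1"]
        assert filtered.column_names == ("X2",)

    def test_all_columns_dropped_is_an_error(self):
        ds = make_dataset(np.zeros((50, 2)), np.tile([0, 1], 25))
        with pytest.raises(ValueError, match="no predictors survive"):
            near_zero_variance_filter(ds)

    def test_idempotent(self):
        ds = balanced(200, 4, seed=3)
        once, _ = near_zero_variance_filter(ds)
        twice, rep = near_zero_variance_filter(once)
        assert rep.dropped_nzv == []
        assert np.array_equal(once.X, twice.X)


class TestCorrelationFilter:
    def test_exact_duplicate_loses_exactly_one_member(self):
        ds = balanced(200, 3, seed=4)
        X = np.column_stack([ds.X, ds.X[:, 0]])
        ds = make_dataset(X, ds.Y)
        filtered, rep = correlation_filter(ds)
        assert len(rep.dropped_correlated) == 1
        assert filtered.n_variables == 3

    def test_perfect_negative_correlation_also_dropped(self):
        ds = balanced(200, 2, seed=5)
        X = np.column_stack([ds.X, 1.0 - ds.X[:, 0]])
        filtered, rep = correlation_filter(make_dataset(X, ds.Y))
        assert len(rep.dropped_correlated) == 1

    def test_independent_bernoulli_columns_survive(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(5000, 3)).astype(float)
        ds = make_dataset(X, np.tile([0, 1], 2500))
        # oracle: the realized correlation matrix itself is far below the cutoff
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.7
        filtered, rep = correlation_filter(ds)
        assert rep.dropped_correlated == []
        assert filtered.n_variables == 3

    def test_no_surviving_pair_above_cutoff_and_idempotent(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 2, size=(300, 4)).astype(float)
        noisy = np.column_stack([base, np.abs(base[:, 0] - (rng.random(300) < 0.05))])
        ds = make_dataset(noisy, np.tile([0, 1], 150))
        filtered, _ = correlation_filter(ds, cutoff=0.7)
        corr = np.corrcoef(filtered.X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.7
        again, rep = correlation_filter(filtered, cutoff=0.7)
        assert rep.dropped_correlated == []


class TestRemoveOutliers:
    def test_null_data_has_no_outliers(self):
        # fitted p near 0.5 bounds every standardized residual near 1
        ds = balanced(300, 3, seed=8)
        filtered, rep = remove_outliers(ds)
        assert rep.dropped_outlier_rows == []
        assert filtered.n_samples == 300

    def test_infinite_cutoff_is_identity(self):
        ds = balanced(300, 3, seed=9)
        filtered, rep = remove_outliers(ds, resid_cut=np.inf)
        assert filtered.n_samples == ds.n_samples

    def test_contradicting_row_with_extreme_fitted_probability_dropped(self):
        # strong planted effects force high fitted p; flip one response to 0
        cfg = SimConfig(
            n_samples=800,
            n_variables=4,
            informative_indices=(0, 1),
            effect_sizes=(4.0, 4.0),
            intercept=-4.0,
            seed=10,
        )
        ds, _ = generate(cfg)
        both = np.nonzero((ds.X[:, 0] == 1) & (ds.X[:, 1] == 1) & (ds.Y == 1))[0]
        y = ds.Y.copy()
        y[both[0]] = 0
        ds = make_dataset(ds.X, y)
        model = fit_logistic(ds)
        p = model.predict_proba(ds.X)
        resid = (ds.Y - p) / np.sqrt(p * (1 - p))  # oracle: direct residual formula
        assert abs(resid[both[0]]) > 3
        _, rep = remove_outliers(ds, model=model)
        assert int(both[0]) in rep.dropped_outlier_rows

    def test_mass_outliers_abort_with_diagnostic(self):
        ds = balanced(100, 2, seed=11)
        with pytest.raises(ValueError, match="misspecification"):
            remove_outliers(ds, resid_cut=0.5)


class TestBinnedResiduals:
    def test_perfect_fit_puts_every_bin_in_band(self):
        # |eta| = 800 saturates the logistic function to exactly 0 or 1
        y = np.tile([0, 1], 50)
        X = np.column_stack([y.astype(float), np.zeros(100)])
        ds = make_dataset(X, y)
        model = FittedLogistic(
            intercept=-800.0,
            coefficients=np.array([1600.0]),
            included_variables=(0,),
            log_likelihood=0.0,
            null_log_likelihood=-69.3,
            n_obs=100,
            converged=True,
            std_errors=np.array([1.0]),
        )
        diag = binned_residuals(model, ds, n_bins=5)
        assert diag.fraction_in_band == 1.0
        assert all(r == 0.0 for _, r, _ in diag.bins)

    def test_band_uses_90pct_normal_multiplier(self):
        ds = balanced(100, 2, seed=12)
        model = fit_logistic(ds)
        diag = binned_residuals(model, ds, n_bins=4, band_level=0.90)
        # oracle: half-width must equal 1.6449 * sd / sqrt(bin size)
        z = stats.norm.ppf(0.95)
        assert z == pytest.approx(1.6449, abs=1e-4)
        p = model.predict_proba(ds.X)
        resid = ds.Y - p
        order = np.argsort(p, kind="stable")
        chunk = np.array_split(order, 4)[0]
        expected = z * resid[chunk].std(ddof=1) / np.sqrt(chunk.size)
        assert diag.bins[0][2] == pytest.approx(expected, abs=1e-12)

    def test_well_specified_model_mostly_inside_band(self):
        cfg = SimConfig(
            n_samples=2000,
            n_variables=1,
            informative_indices=(0,),
            effect_sizes=(1.0,),
            intercept=-0.5,
            seed=13,
        )
        ds, _ = generate(cfg)
        model = fit_logistic(ds, [0])
        diag = binned_residuals(model, ds)
        assert diag.fraction_in_band >= 0.8

    def test_too_few_bins_rejected(self, small_dataset):
        model = fit_logistic(small_dataset, [0])
        with pytest.raises(ValueError):
            binned_residuals(model, small_dataset, n_bins=1)


def test_pipeline_runs_all_three_filters_in_order():
    rng = np.random.default_rng(14)
    base = rng.integers(0, 2, size=(400, 5)).astype(float)
    rare = np.zeros(400)
    rare[0] = 1.0
    dup = base[:, 0]
    X = np.column_stack([base, rare, dup])
    ds = make_dataset(X, np.tile([0, 1], 200))
    cleaned, report = preprocess_pipeline(ds)
    assert "X6" in report.dropped_nzv
    assert len(report.dropped_correlated) == 1
    assert cleaned.n_variables == 5
    assert set(report.surviving_columns) == set(cleaned.column_names)
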