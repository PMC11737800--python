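import numpy as np
import pytest

from carslogit import SimConfig, assess_model, cv_deviance, fit_logistic, generate, odds_ratio_table
from carslogit.data_model import FittedLogistic
from carslogit.logistic_core import null_log_likelihood

from conftest import make_dataset

# intercept-only log-likelihood for n=10 with 4 ones: 4 ln 0.4 + 6 ln 0.6
LL0_10_4 = -6.730117


def _intercept_only_proxy(ll, ll0, n, k=1):
    return FittedLogistic(
        intercept=0.0,
        coefficients=np.zeros(k - 1),
        included_variables=tuple(range(k - 1)),
        log_likelihood=ll,
        null_log_likelihood=ll0,
        n_obs=n,
        converged=True,
        std_errors=np.zeros(k - 1),
    )


class TestFitLogistic:
    def test_intercept_only_matches_closed_form(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        X = np.column_stack([np.arange(10) % 2, np.arange(10) // 5])
        ds = make_dataset(X, y)
        m = fit_logistic(ds, [])
        assert m.log_likelihood == pytest.approx(LL0_10_4, abs=1e-5)
        assert m.null_log_likelihood == pytest.approx(m.log_likelihood, abs=1e-6)
        # fitted probability equals the event rate
        assert m.predict_proba(X)[0] == pytest.approx(0.4, abs=1e-8)

    def test_perfect_separation_triggers_ridge_fallback(self):
        y = np.array([0, 1] * 10)
        X = np.column_stack([y, np.random.default_rng(0).integers(0, 2, 20)])
        ds = make_dataset(X, y)
        m = fit_logistic(ds, [0])
        assert m.used_ridge_fallback
        # ridge fit still orders the classes correctly
        assert m.coefficients[0] > 0

    def test_single_class_rows_rejected(self):
        ds = make_dataset(np.zeros((12, 2)), np.ones(12, dtype=int))
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(ds, [0])

    def test_rank_deficient_design_names_aliased_column(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 40).astype(float)
        X = np.column_stack([x, x])  # exact alias
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        ds = make_dataset(X, y)
        with pytest.raises(ValueError, match="aliased"):
            fit_logistic(ds, [0, 1])

    def test_adding_a_column_never_decreases_log_likelihood(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(60, 150))
            X = rng.integers(0, 2, size=(n, 4)).astype(float)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            ds = make_dataset(X, y)
            lls = [fit_logistic(ds, list(range(k))).log_likelihood for k in range(5)]
            assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestAssessModel:
    def test_null_model_has_zero_pseudo_r2(self):
        m = _intercept_only_proxy(LL0_10_4, LL0_10_4, 10)
        a = assess_model(m)
        assert a.mcfadden_r2 == pytest.approx(0.0, abs=1e-12)
        assert a.cox_snell_r2 == pytest.approx(0.0, abs=1e-12)

    def test_aic_bic_closed_forms(self):
        a = assess_model(_intercept_only_proxy(LL0_10_4, LL0_10_4, 10))
        assert a.aic == pytest.approx(15.460234, abs=1e-5)
        assert a.bic == pytest.approx(15.762819, abs=1e-5)

    def test_cox_snell_at_perfect_fit(self):
        # direct evaluation: 1 - exp(2*(4 ln 0.4 + 6 ln 0.6)/10) = 0.7397268
        a = assess_model(_intercept_only_proxy(0.0, LL0_10_4, 10))
        assert a.cox_snell_r2 == pytest.approx(0.7397268, abs=1e-5)

    def test_closed_form_null_log_likelihood(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        assert null_log_likelihood(y) == pytest.approx(LL0_10_4, abs=1e-5)


class TestOddsRatios:
    def test_zero_coefficient_gives_unit_or(self, small_dataset):
        m = fit_logistic(small_dataset, [0, 1])
        proxy = FittedLogistic(
            intercept=m.intercept,
            coefficients=np.array([0.0, np.log(2.0)]),
            included_variables=(0, 1),
            log_likelihood=m.log_likelihood,
            null_log_likelihood=m.null_log_likelihood,
            n_obs=m.n_obs,
            converged=True,
            std_errors=np.array([0.5, 0.5]),
        )
        rows = odds_ratio_table(proxy, small_dataset)
        assert rows[0].odds_ratio == pytest.approx(1.0, abs=1e-12)
        assert rows[0].ci_low < 1.0 < rows[0].ci_high
        assert rows[1].odds_ratio == pytest.approx(2.0, abs=1e-12)

    def test_wald_ci_uses_normal_quantile(self, small_dataset):
        proxy = FittedLogistic(
            intercept=0.0,
            coefficients=np.array([0.5]),
            included_variables=(0,),
            log_likelihood=-5.0,
            null_log_likelihood=-6.0,
            n_obs=12,
            converged=True,
            std_errors=np.array([0.1]),
        )
        row = odds_ratio_table(proxy, small_dataset, level=0.95)[0]
        assert row.ci_low == pytest.approx(1.35533, abs=1e-4)
        assert row.ci_high == pytest.approx(2.00565, abs=1e-4)

    def test_log_odds_ratio_round_trips_to_coefficient(self, planted_dataset):
        ds, _ = planted_dataset
        m = fit_logistic(ds, [0, 1, 2])
        for j, row in enumerate(odds_ratio_table(m, ds)):
            assert np.log(row.odds_ratio) == pytest.approx(m.coefficients[j], abs=1e-12)


class TestCvDeviance:
    def test_intercept_only_near_bernoulli_entropy(self):
        cfg = SimConfig(n_samples=2000, n_variables=3, intercept=0.0, seed=2)
        ds, _ = generate(cfg)
        dev = cv_deviance(ds, [], k_folds=10, seed=1)
        assert dev == pytest.approx(np.log(2.0), abs=0.02)

    def test_deterministic_given_seed(self, planted_dataset):
        ds, _ = planted_dataset
        a = cv_deviance(ds, [0, 1], k_folds=5, seed=42)
        b = cv_deviance(ds, [0, 1], k_folds=5, seed=42)
        assert a == b

    def test_planted_predictor_beats_intercept_only(self, planted_dataset):
        ds, truth = planted_dataset
        with_signal = cv_deviance(ds, list(truth), k_folds=5, seed=3)
        without = cv_deviance(ds, [], k_folds=5, seed=3)
        assert with_signal < without

    def test_interleaved_folds_and_misclass_loss(self, planted_dataset):
        ds, truth = planted_dataset
        rate = cv_deviance(ds, list(truth), k_folds=5, seed=0, fold_mode="interleaved",
                           loss="misclass")
        assert 0.0 <= rate <= 0.5

    def test_too_many_folds_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="smaller k"):
            cv_deviance(small_dataset, [0], k_folds=10, seed=0)
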