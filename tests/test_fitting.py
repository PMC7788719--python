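"""Analysis model fits: likelihood optima, coding, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import ordprofile as op
from ordprofile.fitting import DesignSpec, FitError, fit_binary_logistic, \
    fit_proportional_odds


def _independent_po_negloglik(y, X, K):
    """Cumulative-logit negative log-likelihood written independently of
    the package fitter (direct probability arithmetic)."""
    def nll(psi):
        alpha = psi[:K - 1]
        beta = psi[K - 1:]
        eta = X @ beta if X.size else np.zeros(len(y))
        total = 0.0
        for yi, ei in zip(y, eta):
            upper = 1.0 if yi == 1 else expit(alpha[yi - 2] + ei)
            lower = 0.0 if yi == K else expit(alpha[yi - 1] + ei)
            p = upper - lower
            if p <= 0:
                return np.inf
            total -= np.log(p)
        return total
    return nll


class TestBinaryLogistic:
    def test_intercept_only_closed_form(self):
        """Intercept of an intercept-only fit equals the sample log-odds
        (4949 good outcomes out of 9578)."""
        y = np.repeat([1, 0], [4949, 4629])
        df = pd.DataFrame({"hospital_id": 1, "outcome": y})
        fit = fit_binary_logistic(df)
        assert fit.intercept == pytest.approx(np.log(4949 / 4629), abs=1e-8)
        assert fit.center_effects.tolist() == [0.0]

    def test_two_by_two_log_odds_ratio(self):
        """Single binary covariate: coefficient equals the table log OR."""
        x = np.repeat([0, 1], 100)
        y = np.concatenate([np.repeat([1, 0], [30, 70]),
                            np.repeat([1, 0], [60, 40])])
        df = pd.DataFrame({"hospital_id": 1, "x": x, "outcome": y})
        fit = fit_binary_logistic(df, DesignSpec(covariates=("x",)))
        log_or = np.log((60 / 40) / (30 / 70))
        assert fit.covariate_coefs["x"] == pytest.approx(log_or, abs=1e-8)

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"hospital_id": [1, 1, 2, 2],
                           "outcome": [1, 1, 1, 1]})
        with pytest.raises(FitError):
            fit_binary_logistic(df)

    def test_separated_hospital_marked_non_estimable(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "hospital_id": np.repeat([1, 2, 3], 40),
            "outcome": np.concatenate([rng.integers(0, 2, 80),
                                       np.ones(40, dtype=int)]),
        })
        fit = fit_binary_logistic(df)
        assert fit.non_estimable == (3,)
        assert np.isnan(fit.center_effects[2])
        est = fit.center_effects[fit.estimable]
        assert est.sum() == pytest.approx(0.0, abs=1e-8)


class TestProportionalOdds:
    def test_k2_equals_binary_logistic(self, small_cohort, impact):
        cohort, _ = small_cohort
        df = cohort.data.copy()
        design = DesignSpec(covariates=("age", "pupils"))
        df["outcome"] = op.dichotomize(cohort.outcomes(), impact.scale,
                                       "favorable")
        fb = fit_binary_logistic(df, design)
        fo = fit_proportional_odds(df.assign(outcome=df["outcome"] + 1),
                                   design, n_categories=2)
        assert fo.loglik == pytest.approx(fb.loglik, abs=1e-6)
        np.testing.assert_allclose(fo.center_effects, fb.center_effects,
                                   atol=1e-6)
        np.testing.assert_allclose(fo.se, fb.se, atol=1e-6)

    def test_tiny_dataset_matches_derivative_free_oracle(self):
        """Newton optimum equals a Powell search on an independently
        written likelihood, on a 24-row, 3-category, 2-hospital set."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "hospital_id": np.repeat([1, 2], 12),
            "x": rng.normal(size=24).round(2),
            "outcome": rng.integers(1, 4, size=24),
        })
        # ensure all categories observed
        df.loc[:2, "outcome"] = [1, 2, 3]
        fit = fit_proportional_odds(df, DesignSpec(covariates=("x",)),
                                    n_categories=3)
        x = df["x"].to_numpy()
        X = np.column_stack([x - x.mean(),
                             (df["hospital_id"] == 2).astype(float)])
        nll = _independent_po_negloglik(df["outcome"].to_numpy(), X, 3)
        res = minimize(nll, np.array([0.5, -0.5, 0.0, 0.0]),
                       method="Powell",
                       options={"xtol": 1e-12, "ftol": 1e-14,
                                "maxfev": 100_000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert fit.loglik >= -res.fun - 1e-6

    def test_matches_statsmodels_ordered_model(self, small_cohort):
        """Independent library cross-check of coefficients and loglik."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        cohort, _ = small_cohort
        df = cohort.data
        fit = fit_proportional_odds(df, DesignSpec(covariates=("age",)),
                                    n_categories=4)
        X = pd.DataFrame({"age": df["age"] - df["age"].mean()})
        for h in sorted(df["hospital_id"].unique())[1:]:
            X[f"h{h}"] = (df["hospital_id"] == h).astype(float)
        res = OrderedModel(df["outcome"], X, distr="logit").fit(
            method="bfgs", disp=False, maxiter=1000)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-5)
        b = np.concatenate([[0.0], res.params[1:1 + 4]])
        np.testing.assert_allclose(
            fit.center_effects, b - b.mean(), atol=1e-4)

    def test_parameter_recovery_large_n(self, impact):
        """True deviations (+-0.5, +-0.25) recovered within +-0.03 at
        n = 100k per hospital."""
        beta = np.array([0.5, -0.5, 0.25, -0.25])
        eff = op.CenterEffectVector(beta, 0.35, "A")
        coh = op.simulate_cohort(impact.generator, None, 4, 100_000,
                                 eff, 13)
        fit = fit_proportional_odds(coh.data, DesignSpec(),
                                    n_categories=4)
        np.testing.assert_allclose(fit.center_effects,
                                   beta - beta.mean(), atol=0.03)

    def test_reversed_categories_flip_sign(self, small_cohort):
        """Reversing the category order negates effects up to sign."""
        cohort, _ = small_cohort
        df = cohort.data
        fit = fit_proportional_odds(df, n_categories=4)
        rev = df.assign(outcome=5 - df["outcome"])
        fit_rev = fit_proportional_odds(rev, n_categories=4)
        assert fit_rev.loglik == pytest.approx(fit.loglik, abs=1e-6)
        np.testing.assert_allclose(fit_rev.center_effects,
                                   -fit.center_effects, atol=1e-6)

    def test_all_bottom_hospital_non_estimable(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "hospital_id": np.repeat([1, 2, 3], 30),
            "outcome": np.concatenate([rng.integers(1, 5, 60),
                                       np.ones(30, dtype=int)]),
        })
        fit = fit_proportional_odds(df, n_categories=4)
        assert fit.non_estimable == (3,)

    def test_unobserved_category_merged_with_warning(self):
        df = pd.DataFrame({
            "hospital_id": np.repeat([1, 2], 30),
            "outcome": np.tile([1, 2, 4], 20),  # category 3 empty
        })
        with pytest.warns(UserWarning, match="unobserved"):
            fit = fit_proportional_odds(df, n_categories=4)
        assert fit.converged
        assert len(fit.thresholds) == 2

    def test_se_shrinks_with_sqrt_n(self, impact):
        """Doubling patients per hospital shrinks the median SE ~ sqrt(2)."""
        ses = []
        for n, seed in [(400, 21), (1600, 22)]:
            eff = op.sample_center_effects(6, 0.35, "A", 20)
            coh = op.simulate_cohort(impact.generator, None, 6, n, eff,
                                     seed)
            fit = fit_proportional_odds(coh.data, n_categories=4)
            ses.append(np.nanmedian(fit.se))
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.10)


def test_deviations_sum_to_zero_and_marginal_se_larger(small_cohort):
    cohort, _ = small_cohort
    fit = fit_proportional_odds(cohort.data, n_categories=4)
    assert np.nansum(fit.center_effects) == pytest.approx(0.0, abs=1e-8)
    # reference-coded SEs ignore the hospital-vs-mean correlation and are
    # systematically larger than the deviation SEs
    assert np.nanmedian(fit.se_marginal) > np.nanmedian(fit.se)
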