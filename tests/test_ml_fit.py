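"""Estimation: closed-form OLS equivalence, likelihood oracles, constrained fits."""

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm

from mbco import (
    ConstraintSpec,
    coef_covariance,
    fit_full,
    fit_null,
    log_likelihood,
)
from mbco.exceptions import EstimationError, InputDataError
from mbco.ml_fit import _loglik_equations

from _helpers import make_params, ols_refit


class TestFullFit:
    def test_matches_closed_form_ols(self, general_model, data50):
        fit = fit_full(general_model, data50)
        betas, psis, ll = ols_refit(general_model, data50)
        for lab, val in betas.items():
            assert fit.params.betas[lab] == pytest.approx(val, abs=1e-6)
        for lab, val in psis.items():
            assert fit.params.psis[lab] == pytest.approx(val, rel=1e-8)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6)

    def test_coefficients_shrink_to_zero_under_null(self, chain_model):
        from mbco import GenerationConfig, simulate_dataset

        data = simulate_dataset(chain_model, GenerationConfig(beta=0.0, n=50_000, seed=5))
        fit = fit_full(chain_model, data)
        for lab in ("b1", "b2", "b3"):
            assert abs(fit.params.betas[lab]) < 0.02

    def test_saturated_equation_errors_instead_of_fitting(self, general_model, data50):
        with pytest.raises(EstimationError):
            fit_full(general_model, data50.head(4))

    def test_missing_values_rejected(self, chain_model, data_h1):
        bad = data_h1.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(InputDataError):
            fit_full(chain_model, bad)

    def test_missing_column_rejected(self, chain_model, data_h1):
        with pytest.raises(InputDataError):
            fit_full(chain_model, data_h1.drop(columns=["M2"]))


class TestLogLikelihood:
    def test_single_standard_normal_row(self):
        from mbco import PathModel

        m = PathModel.from_strings(["M1 ~ b1*X"])
        params = make_params(m)
        import pandas as pd

        row = pd.DataFrame({"M1": [0.0], "X": [0.0]})
        assert log_likelihood(m, params, row) == pytest.approx(-np.log(2 * np.pi))

    def test_matches_multivariate_normal_density_oracle(self, general_model, data50, rng):
        from mbco import implied_moments

        params = make_params(
            general_model,
            betas={"b1": 0.3, "b2": -0.2, "b3": 0.4, "b4": 0.1, "b5": 0.0, "b6": -0.3},
            psis={general_model.variance_label("Y"): 0.5},
        )
        mom = implied_moments(general_model, params)
        arr = data50[list(general_model.variables)].to_numpy()
        oracle = scipy.stats.multivariate_normal(mom.mean, mom.covariance).logpdf(arr).sum()
        assert log_likelihood(general_model, params, data50) == pytest.approx(oracle)

    def test_joint_equals_equationwise_factorization(self, general_model, data50):
        params = make_params(general_model, betas={"b1": 0.2, "b3": -0.5})
        joint = log_likelihood(general_model, params, data50)
        by_eq = _loglik_equations(general_model, params, data50)
        assert joint == pytest.approx(by_eq, abs=1e-8)

    def test_invariant_to_row_order(self, general_model, data50):
        params = make_params(general_model)
        shuffled = data50.sample(frac=1.0, random_state=1)
        assert log_likelihood(general_model, params, data50) == pytest.approx(
            log_likelihood(general_model, params, shuffled)
        )


class TestNullFit:
    def test_null_never_beats_full(self, general_model, data50, data_h1, chain_model):
        for model, data in [(general_model, data50), (chain_model, data_h1)]:
            full = fit_full(model, data)
            null = fit_null(model, data)
            assert null.log_likelihood <= full.log_likelihood + 1e-6
            assert null.constraint_violation <= 1e-8

    def test_matches_profile_grid_oracle(self, general_model, data50):
        """Null LL = best over fixing each of b1, b2, b3 to zero (OLS route)."""
        oracle = max(
            ols_refit(general_model, data50, drop_label=lab)[2] for lab in ("b1", "b2", "b3")
        )
        null = fit_null(general_model, data50)
        assert null.log_likelihood == pytest.approx(oracle, abs=1e-4)

    def test_slsqp_solver_agrees_with_exact_branch(self, general_model, data50):
        exact = fit_null(general_model, data50)
        generic = fit_null(general_model, data50, solver="slsqp")
        assert generic.log_likelihood == pytest.approx(exact.log_likelihood, abs=1e-5)
        assert generic.constraint_violation <= 1e-8

    def test_self_constraint_reproduces_full_fit(self, general_model, data50):
        full = fit_full(general_model, data50)
        c = full.params.product(("b1", "b2", "b3"))
        null = fit_null(
            general_model, data50, ConstraintSpec(("b1", "b2", "b3"), c)
        )
        assert null.log_likelihood == pytest.approx(full.log_likelihood, abs=1e-6)

    def test_nonzero_constant_reduced_solver(self, general_model, data50):
        # profiled SLSQP hits the constraint surface and stays below full LL
        full = fit_full(general_model, data50)
        c = 0.5 * full.params.product(("b1", "b2", "b3"))
        null = fit_null(general_model, data50, ConstraintSpec(("b1", "b2", "b3"), c))
        assert null.constraint_violation <= 1e-8
        assert null.log_likelihood < full.log_likelihood

    def test_variances_stay_positive(self, general_model, data50):
        null = fit_null(general_model, data50)
        assert all(p > 1e-10 for p in null.params.psis.values())


class TestCoefCovariance:
    def test_matches_numeric_hessian_of_joint_likelihood(self, general_model, data50):
        """Observed-information covariance equals the inverse numeric Hessian."""
        fit = fit_full(general_model, data50)
        labels = ("b1", "b2", "b3")
        block = coef_covariance(fit, labels)
        # numeric Hessian of the joint LL in the three coefficients, with all
        # other parameters held at their MLEs, is NOT the right comparison
        # (nuisance parameters must be profiled); instead compare against the
        # per-equation OLS covariance computed independently via statsmodels
        n = len(data50)
        for i, (lab, var, preds) in enumerate(
            [("b1", "M1", ["X"]), ("b2", "M2", ["M1", "X"]), ("b3", "Y", ["M2", "M1", "X"])]
        ):
            X = sm.add_constant(data50[preds].to_numpy())
            res = sm.OLS(data50[var].to_numpy(), X).fit()
            # statsmodels uses divisor (n-k); rescale to the ML variance
            ml_cov = res.cov_params() * (res.ssr / n) / res.mse_resid
            assert block[i, i] == pytest.approx(ml_cov[1, 1], rel=1e-8)
        # coefficients from different equations are uncorrelated
        off = block[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)
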