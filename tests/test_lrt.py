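"""MBCO LRT variants: statistic, reference distributions, bootstrap mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, kstest

from mbco import (
    ConstraintSpec,
    asymptotic_mbco,
    fit_full,
    fit_null,
    implied_moments,
    parametric_bootstrap_mbco,
    semiparametric_bootstrap_mbco,
    semiparametric_transform,
)
from mbco.lrt import _bootstrap_pvalue


class TestAsymptotic:
    def test_chi_square_reference_values(self, chain_model, data_h1):
        res = asymptotic_mbco(chain_model, data_h1)
        assert res.df == 1
        assert res.p_value == pytest.approx(chi2.sf(res.statistic, 1))
        # the canonical critical value: upper-tail p at 3.841 is 0.05
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)
        assert chi2.sf(0.0, 1) == 1.0

    def test_detects_true_indirect_effect(self, chain_model, data_h1):
        assert asymptotic_mbco(chain_model, data_h1).p_value < 0.01

    def test_statistic_zero_when_constraint_holds_at_mle(self, chain_model, data_h1):
        c = fit_full(chain_model, data_h1).params.product(("b1", "b2", "b3"))
        res = asymptotic_mbco(
            chain_model, data_h1, ConstraintSpec(("b1", "b2", "b3"), c)
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_single_zero_null_is_chi_square_one(self, chain_model):
        """On the regular part of the composite null (only b1 = 0) the
        statistic follows chi-square(1); KS distance and rejection rate
        both confirm the asymptotic reference distribution."""
        from mbco import GenerationConfig, simulate_dataset

        stats = []
        for ss in np.random.SeedSequence(2024).spawn(400):
            rng = np.random.default_rng(ss)
            data = simulate_dataset(
                chain_model,
                GenerationConfig(beta=0.0, n=500, overrides={"b2": 0.36, "b3": 0.36}),
                rng=rng,
            )
            stats.append(asymptotic_mbco(chain_model, data).statistic)
        stats = np.asarray(stats)
        assert kstest(stats, chi2(1).cdf).statistic < 0.06
        rate = np.mean(stats > chi2.ppf(0.95, 1))
        assert 0.025 <= rate <= 0.075  # Bradley's liberal criterion


class TestSemiparametricTransform:
    def test_transformed_covariance_equals_null_implied(self, chain_model, data_h1, rng):
        arr = data_h1.to_numpy()
        null = fit_null(chain_model, data_h1)
        mom = implied_moments(chain_model, null.params)
        star = semiparametric_transform(
            data_h1[list(chain_model.variables)].to_numpy(), mom.mean, mom.covariance
        )
        assert np.allclose(np.cov(star, rowvar=False, ddof=1), mom.covariance, atol=1e-10)
        assert np.allclose(star.mean(axis=0), mom.mean, atol=1e-10)

    def test_identity_when_target_is_sample_covariance(self, rng):
        arr = rng.standard_normal((60, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
        ybar = arr.mean(axis=0)
        S = np.cov(arr, rowvar=False, ddof=1)
        star = semiparametric_transform(arr, ybar, S)
        assert np.allclose(star, arr, atol=1e-8)

    def test_arbitrary_pd_target(self, rng):
        arr = rng.standard_normal((40, 3))
        A = rng.standard_normal((3, 3))
        target = A @ A.T + 3.0 * np.eye(3)
        star = semiparametric_transform(arr, np.zeros(3), target)
        assert np.allclose(np.cov(star, rowvar=False, ddof=1), target, atol=1e-10)


class TestBootstrapTests:
    @pytest.mark.parametrize("runner", [parametric_bootstrap_mbco, semiparametric_bootstrap_mbco])
    def test_rejects_n_boot_below_one(self, runner, chain_model, data_h1):
        with pytest.raises(ValueError):
            runner(chain_model, data_h1, n_boot=0)

    @pytest.mark.parametrize("runner", [parametric_bootstrap_mbco, semiparametric_bootstrap_mbco])
    def test_p_near_one_when_observed_statistic_zero(self, runner, chain_model, data_h1):
        c = fit_full(chain_model, data_h1).params.product(("b1", "b2", "b3"))
        res = runner(
            chain_model, data_h1, ConstraintSpec(("b1", "b2", "b3"), c), n_boot=49, seed=0
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.9  # every bootstrap statistic exceeds ~0

    @pytest.mark.parametrize("runner", [parametric_bootstrap_mbco, semiparametric_bootstrap_mbco])
    def test_same_seed_reproduces_same_p(self, runner, chain_model, data_h0):
        a = runner(chain_model, data_h0, n_boot=49, seed=11)
        b = runner(chain_model, data_h0, n_boot=49, seed=11)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_sample, b.null_sample)

    def test_all_methods_share_the_statistic(self, chain_model, data_h0):
        asym = asymptotic_mbco(chain_model, data_h0)
        par = parametric_bootstrap_mbco(chain_model, data_h0, n_boot=19, seed=1)
        semi = semiparametric_bootstrap_mbco(chain_model, data_h0, n_boot=19, seed=1)
        assert par.statistic == pytest.approx(asym.statistic, abs=1e-10)
        assert semi.statistic == pytest.approx(asym.statistic, abs=1e-10)

    def test_bookkeeping_of_failures(self, chain_model, data_h0):
        res = parametric_bootstrap_mbco(chain_model, data_h0, n_boot=37, seed=3)
        assert len(res.null_sample) + res.n_boot_failures == 37

    def test_corrected_p_value_option(self, chain_model, data_h0):
        plain = semiparametric_bootstrap_mbco(chain_model, data_h0, n_boot=49, seed=2)
        corr = semiparametric_bootstrap_mbco(
            chain_model, data_h0, n_boot=49, seed=2, corrected=True
        )
        b = int(np.sum(plain.null_sample > plain.statistic))
        assert plain.p_value == b / 49
        assert corr.p_value == (b + 1) / 50

    def test_parametric_p_values_uniform_under_null(self, chain_model):
        """Under the regular null (b1=0, b2=b3 nonzero) the parametric
        bootstrap p-value is approximately uniform."""
        from mbco import GenerationConfig, simulate_dataset

        pvals = []
        for ss in np.random.SeedSequence(77).spawn(150):
            rng = np.random.default_rng(ss)
            data = simulate_dataset(
                chain_model,
                GenerationConfig(beta=0.0, n=200, overrides={"b2": 0.36, "b3": 0.36}),
                rng=rng,
            )
            pvals.append(
                parametric_bootstrap_mbco(chain_model, data, n_boot=99, seed=rng).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    t_obs=st.floats(0.0, 20.0),
    shift=st.floats(0.0, 5.0),
)
def test_bootstrap_p_nonincreasing_in_observed_statistic(t_obs, shift):
    sample = np.linspace(0.01, 15.0, 200)
    assert _bootstrap_pvalue(t_obs + shift, sample, False) <= _bootstrap_pvalue(
        t_obs, sample, False
    )
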