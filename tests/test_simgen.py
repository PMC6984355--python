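"""Synthetic-data generator: Fleishman moments, standardization, determinism."""

import numpy as np
import pytest
from scipy.stats import kurtosis, skew

from mbco import (
    GenerationConfig,
    fleishman_coefficients,
    simulate_dataset,
)
from mbco.exceptions import InfeasibleMomentsError, ModelSpecificationError
from mbco.simgen import (
    MODERATE_NONNORMAL,
    SEVERE_NONNORMAL,
    standardized_residual_variances,
)


class TestFleishman:
    def test_normal_case_is_identity(self):
        assert fleishman_coefficients(0.0, 0.0) == (0.0, 1.0, 0.0, 0.0)

    def test_moment_equations_satisfied_exactly(self):
        for sk, ku in [(2.0, 7.0), (3.0, 21.0), (-2.0, 7.0), (1.0, 3.0)]:
            a, b, c, d = fleishman_coefficients(sk, ku)
            assert a == -c
            # analytic moments of a + bZ + cZ^2 + dZ^3
            var = b * b + 6 * b * d + 2 * c * c + 15 * d * d
            skew_ = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2)
            kurt_ = 24 * (
                b * d
                + c * c * (1 + b * b + 28 * b * d)
                + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
            )
            assert var == pytest.approx(1.0, abs=1e-10)
            assert skew_ == pytest.approx(sk, abs=1e-10)
            assert kurt_ == pytest.approx(ku, abs=1e-10)

    def test_moderate_sample_moments(self):
        a, b, c, d = fleishman_coefficients(2.0, 7.0)
        z = np.random.default_rng(0).standard_normal(1_000_000)
        e = a + b * z + c * z * z + d * z**3
        assert skew(e) == pytest.approx(2.0, abs=0.05)
        assert kurtosis(e) == pytest.approx(7.0, abs=0.3)

    def test_severe_sample_moments(self):
        a, b, c, d = fleishman_coefficients(3.0, 21.0)
        z = np.random.default_rng(0).standard_normal(1_000_000)
        e = a + b * z + c * z * z + d * z**3
        assert skew(e) == pytest.approx(3.0, abs=0.05)
        assert kurtosis(e) == pytest.approx(21.0, abs=1.0)

    def test_infeasible_pair_raises(self):
        # excess kurtosis below skew^2 - 2 is impossible for any distribution
        with pytest.raises(InfeasibleMomentsError):
            fleishman_coefficients(3.0, 4.0)


class TestStandardization:
    def test_unit_variances_chain(self, chain_model):
        psis = standardized_residual_variances(
            chain_model, {"b1": 0.36, "b2": 0.36, "b3": 0.36}
        )
        for v in ("M1", "M2", "Y"):
            assert psis[chain_model.variance_label(v)] == pytest.approx(1 - 0.36**2)

    def test_direct_paths_enter_structural_variance(self, general_model):
        betas = {"b1": 0.3, "b2": 0.3, "b3": 0.3, "b4": 0.2, "b5": 0.0, "b6": 0.0}
        psis = standardized_residual_variances(general_model, betas)
        # var(M2) = b2^2 + b4^2 + 2 b2 b4 cov(M1,X) + psi = 1
        expect = 1 - (0.3**2 + 0.2**2 + 2 * 0.3 * 0.2 * 0.3)
        assert psis[general_model.variance_label("M2")] == pytest.approx(expect)

    def test_oversized_coefficients_rejected(self, chain_model):
        with pytest.raises(ModelSpecificationError):
            standardized_residual_variances(chain_model, {"b1": 1.2, "b2": 0.0, "b3": 0.0})


class TestSimulateDataset:
    def test_deterministic_under_seed(self, chain_model):
        cfg = GenerationConfig(beta=0.36, n=100, seed=99)
        a = simulate_dataset(chain_model, cfg)
        b = simulate_dataset(chain_model, cfg)
        assert a.equals(b)

    def test_sample_correlation_matches_implied(self, chain_model):
        data = simulate_dataset(chain_model, GenerationConfig(beta=0.36, n=100_000, seed=1))
        assert np.corrcoef(data.X, data.M1)[0, 1] == pytest.approx(0.36, abs=0.01)
        assert data[["M1", "M2", "Y"]].var(ddof=0).to_numpy() == pytest.approx(
            np.ones(3), abs=0.02
        )

    def test_null_config_gives_uncorrelated_columns(self, chain_model):
        data = simulate_dataset(chain_model, GenerationConfig(beta=0.0, n=100_000, seed=2))
        corr = data.corr().to_numpy()
        assert np.max(np.abs(corr - np.eye(4))) < 0.02

    @pytest.mark.parametrize("dist", [MODERATE_NONNORMAL, SEVERE_NONNORMAL])
    @pytest.mark.parametrize("mode", ["observed", "residual"])
    def test_nonnormal_marginal_moments(self, chain_model, dist, mode):
        cfg = GenerationConfig(
            beta=0.36, n=300_000, distribution=dist, seed=3, nonnormal_mode=mode
        )
        data = simulate_dataset(chain_model, cfg)
        if mode == "observed":
            cols = data
        else:  # residual mode targets the shocks; check the exogenous X
            cols = data[["X"]]
        tol_skew = 0.15 if dist is MODERATE_NONNORMAL else 0.4
        tol_kurt = 0.8 if dist is MODERATE_NONNORMAL else 5.0
        for col in cols:
            assert skew(data[col]) == pytest.approx(dist.skewness, abs=tol_skew)
            assert kurtosis(data[col]) == pytest.approx(dist.kurtosis, abs=tol_kurt)

    def test_observed_mode_preserves_implied_covariance(self, chain_model):
        cfg = GenerationConfig(beta=0.36, n=300_000, distribution=MODERATE_NONNORMAL, seed=4)
        data = simulate_dataset(chain_model, cfg)
        assert np.corrcoef(data.X, data.M1)[0, 1] == pytest.approx(0.36, abs=0.015)
        assert np.corrcoef(data.M2, data.Y)[0, 1] == pytest.approx(0.36, abs=0.015)

    def test_normal_residual_columns_are_normal(self, chain_model):
        data = simulate_dataset(chain_model, GenerationConfig(beta=0.36, n=200_000, seed=5))
        assert skew(data.X) == pytest.approx(0.0, abs=0.03)
        assert kurtosis(data.X) == pytest.approx(0.0, abs=0.05)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            GenerationConfig(beta=0.1, n=5)
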