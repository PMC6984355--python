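"""Model-based constrained-optimization (MBCO) likelihood-ratio tests.

The MBCO LRT compares the full recursive mediation model against a null
model estimated by maximizing the same normal likelihood subject to the
scalar constraint g(beta) = b1 b2 b3 = 0:

    T = -2 [ LL(null MLE) - LL(full MLE) ]  >= 0.

Three reference distributions for T are provided:

* **asymptotic** — chi-square with df = number of independent equality
  constraints (1 for the product constraint); upper-tail p-value.
* **parametric bootstrap** — draw samples of size N from the normal
  distribution with the fitted *null* model's implied mean and
  covariance, recompute T on each, and take the p-value as the
  proportion of bootstrap statistics greater than the observed T.
* **semi-parametric bootstrap** — linearly transform the observed rows
  so their sample covariance equals the null model's implied covariance
  (a Bollen-Stine-style rotation through the Cholesky factors of S and
  Sigma0), resample rows with replacement, recompute T; same p-value
  rule.

The test rejects for large T.  Bootstrap replications whose fits fail
are dropped (never imputed) and counted in ``n_boot_failures``; the
p-value denominator is the number of successful replications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2

from .exceptions import EstimationError, InputDataError, InternalConsistencyError
from .ml_fit import (
    FitResult,
    SuffStats,
    _fit_full_suff,
    _fit_null_suff,
    _resolve_constraint,
    fit_full,
    fit_null,
)
from .path_model import ConstraintSpec, PathModel, implied_moments

__all__ = [
    "LRTResult",
    "asymptotic_mbco",
    "parametric_bootstrap_mbco",
    "semiparametric_bootstrap_mbco",
    "semiparametric_transform",
]

#: fraction of failed bootstrap fits beyond which the result is flagged
MAX_FAILURE_FRACTION = 0.10


@dataclass(frozen=True)
class LRTResult:
    """Outcome of an MBCO likelihood-ratio test."""

    statistic: float
    df: int
    p_value: float
    method: str
    full_fit: FitResult
    null_fit: FitResult
    null_sample: np.ndarray | None = None
    n_boot_failures: int = 0
    unreliable: bool = False

    def __post_init__(self) -> None:
        assert self.statistic >= 0.0
        assert 0.0 <= self.p_value <= 1.0

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _lrt_statistic(full: FitResult, null: FitResult) -> float:
    t = -2.0 * (null.log_likelihood - full.log_likelihood)
    if t < -1e-6:
        raise InternalConsistencyError(
            f"negative LRT statistic {t:.3e}: null fit beats full fit"
        )
    return max(t, 0.0)


def asymptotic_mbco(
    model: PathModel,
    data: pd.DataFrame | np.ndarray,
    constraint: ConstraintSpec | None = None,
    solver: str = "auto",
) -> LRTResult:
    """Asymptotic MBCO LRT: T referred to its limiting chi-square(df)."""
    full = fit_full(model, data)
    null = fit_null(model, data, constraint, solver=solver)
    return _asymptotic_from_fits(full, null)


def _asymptotic_from_fits(full: FitResult, null: FitResult) -> LRTResult:
    t = _lrt_statistic(full, null)
    df = 1  # one independent equality constraint g(beta) = c
    return LRTResult(
        statistic=t,
        df=df,
        p_value=float(chi2.sf(t, df)),
        method="asymptotic",
        full_fit=full,
        null_fit=null,
    )


def _bootstrap_pvalue(t_obs: float, t_star: np.ndarray, corrected: bool) -> float:
    b = int(np.sum(t_star > t_obs))
    if corrected:
        return (b + 1) / (len(t_star) + 1)
    return b / len(t_star)


def _boot_lrt(model: PathModel, arr: np.ndarray, constraint: ConstraintSpec) -> float:
    suff = SuffStats.from_array(arr, model.variables)
    full = _fit_full_suff(model, suff)
    null = _fit_null_suff(model, suff, constraint)
    return _lrt_statistic(full, null)


def _finalize_bootstrap(
    asym: LRTResult,
    t_star: list[float],
    n_failures: int,
    n_boot: int,
    method: str,
    corrected: bool,
) -> LRTResult:
    if not t_star:
        raise EstimationError("every bootstrap replication failed")
    unreliable = n_failures > MAX_FAILURE_FRACTION * n_boot
    if unreliable:
        warnings.warn(
            f"{n_failures}/{n_boot} bootstrap fits failed; p-value flagged unreliable",
            RuntimeWarning,
            stacklevel=3,
        )
    sample = np.asarray(t_star)
    return LRTResult(
        statistic=asym.statistic,
        df=asym.df,
        p_value=_bootstrap_pvalue(asym.statistic, sample, corrected),
        method=method,
        full_fit=asym.full_fit,
        null_fit=asym.null_fit,
        null_sample=sample,
        n_boot_failures=n_failures,
        unreliable=unreliable,
    )


def parametric_bootstrap_mbco(
    model: PathModel,
    data: pd.DataFrame | np.ndarray,
    constraint: ConstraintSpec | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    corrected: bool = False,
) -> LRTResult:
    """Parametric-bootstrap MBCO LRT.

    Draws ``n_boot`` samples of size N from the multivariate normal with
    the fitted null model's implied mean and covariance, refits both
    models on each draw, and takes the p-value as the proportion of
    bootstrap statistics greater than the observed asymptotic T.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    constraint = _resolve_constraint(model, constraint)
    asym = asymptotic_mbco(model, data, constraint)
    mom = implied_moments(model, asym.null_fit.params)
    chol = np.linalg.cholesky(mom.covariance)
    n = asym.full_fit.n_obs
    rng = np.random.default_rng(seed)
    t_star: list[float] = []
    n_failures = 0
    for _ in range(n_boot):
        draw = mom.mean + rng.standard_normal((n, len(mom.mean))) @ chol.T
        try:
            t_star.append(_boot_lrt(model, draw, constraint))
        except EstimationError:
            n_failures += 1
    return _finalize_bootstrap(asym, t_star, n_failures, n_boot, "parametric_bootstrap", corrected)


def semiparametric_transform(
    arr: np.ndarray, mean0: np.ndarray, cov0: np.ndarray
) -> np.ndarray:
    """Rotate rows so their sample covariance equals the null implied covariance.

    With S the divisor-(N-1) sample covariance, factor S = U_S' U_S and
    Sigma0 = U_0' U_0 into upper-triangular Cholesky factors; each
    centered row is mapped by U_0' U_S^{-T} and the null-implied means
    are added back.  By construction cov(y*) (divisor N-1) = Sigma0;
    this identity is verified at runtime to 1e-10.
    """
    n = arr.shape[0]
    if n < 2:
        raise InputDataError("need at least 2 rows")
    ybar = arr.mean(axis=0)
    centered = arr - ybar
    S = centered.T @ centered / (n - 1)
    try:
        u_s = scipy.linalg.cholesky(S, lower=False)
        u_0 = scipy.linalg.cholesky(cov0, lower=False)
    except scipy.linalg.LinAlgError as err:
        raise InputDataError(
            "sample or null-implied covariance is not positive definite"
        ) from err
    # row-wise y*_i = U_0' U_S^{-T} (y_i - ybar) + mu0  <=>  Y* = Yc U_S^{-1} U_0 + mu0
    transformed = centered @ scipy.linalg.solve_triangular(u_s, u_0, lower=False) + mean0
    check = np.cov(transformed, rowvar=False, ddof=1)
    if not np.allclose(check, cov0, atol=1e-10, rtol=0.0):
        raise InternalConsistencyError(
            "transformed-data covariance does not reproduce the null implied covariance"
        )
    return transformed


def semiparametric_bootstrap_mbco(
    model: PathModel,
    data: pd.DataFrame | np.ndarray,
    constraint: ConstraintSpec | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    corrected: bool = False,
) -> LRTResult:
    """Semi-parametric (Bollen-Stine-style) bootstrap MBCO LRT.

    Transforms the observed rows to match the fitted null model's
    implied moments, resamples N rows with replacement ``n_boot`` times,
    refits both models per resample, and takes the p-value as the
    proportion of bootstrap statistics greater than the observed T.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    constraint = _resolve_constraint(model, constraint)
    asym = asymptotic_mbco(model, data, constraint)
    from .ml_fit import _validate_data  # row-level access, not just suff stats

    arr = _validate_data(model, data)
    mom = implied_moments(model, asym.null_fit.params)
    star = semiparametric_transform(arr, mom.mean, mom.covariance)
    n = star.shape[0]
    rng = np.random.default_rng(seed)
    t_star: list[float] = []
    n_failures = 0
    for _ in range(n_boot):
        resample = star[rng.integers(0, n, n)]
        try:
            t_star.append(_boot_lrt(model, resample, constraint))
        except EstimationError:
            n_failures += 1
    return _finalize_bootstrap(
        asym, t_star, n_failures, n_boot, "semiparametric_bootstrap", corrected
    )
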