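"""CI-based tests of the indirect effect: percentile bootstrap, profile
likelihood, and Monte Carlo.

Each method produces a 100(1-alpha)% interval for the indirect effect
(the product of the constrained path coefficients); the associated test
rejects the null of zero indirect effect iff 0 lies outside the
interval.

* **percentile bootstrap** — resample rows with replacement, refit the
  full model per resample, take the alpha/2 and 1-alpha/2 empirical
  quantiles of the resampled products.
* **Monte Carlo** — draw coefficient vectors from the normal
  approximation N(MLEs, asymptotic covariance of the MLEs), multiply
  them, take the same quantiles of the simulated products.
* **profile likelihood** — endpoints are the smallest and largest
  values c of the indirect effect at which
  -2 [ max LL s.t. product = c  -  max LL ] equals the chi-square(1)
  critical value (3.841 at the 95% level).

Empirical quantiles are linear-interpolation (type-7) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from .exceptions import ConvergenceError, EstimationError
from .ml_fit import (
    FitResult,
    SeparableProfile,
    SuffStats,
    _fit_full_suff,
    _fit_null_suff,
    _resolve_constraint,
    _validate_data,
    coef_covariance,
)
from .path_model import ConstraintSpec, PathModel

__all__ = [
    "IntervalResult",
    "monte_carlo_ci",
    "percentile_bootstrap_ci",
    "profile_likelihood_ci",
]

#: |T(endpoint) - chi2 critical value| tolerance at returned profile endpoints
ENDPOINT_TOL = 1e-4


@dataclass(frozen=True)
class IntervalResult:
    """A confidence interval for the indirect effect and its implied test."""

    lower: float
    upper: float
    level: float
    method: str
    point_estimate: float
    n_boot_failures: int = 0

    def __post_init__(self) -> None:
        assert self.lower <= self.upper
        assert 0.0 < self.level < 1.0

    @property
    def rejects_zero(self) -> bool:
        """True iff 0 lies outside [lower, upper]."""
        return not (self.lower <= 0.0 <= self.upper)


def percentile_bootstrap_ci(
    model: PathModel,
    data: pd.DataFrame | np.ndarray,
    constraint: ConstraintSpec | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> IntervalResult:
    """Percentile nonparametric bootstrap CI for the indirect effect."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    constraint = _resolve_constraint(model, constraint)
    arr = _validate_data(model, data)
    full = _fit_full_suff(model, SuffStats.from_array(arr, model.variables))
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    products: list[float] = []
    n_failures = 0
    for _ in range(n_boot):
        resample = arr[rng.integers(0, n, n)]
        try:
            refit = _fit_full_suff(model, SuffStats.from_array(resample, model.variables))
        except EstimationError:
            n_failures += 1
            continue
        products.append(refit.params.product(constraint.labels))
    if not products:
        raise EstimationError("every bootstrap refit failed")
    if n_failures > 0.10 * n_boot:
        warnings.warn(
            f"{n_failures}/{n_boot} bootstrap refits failed", RuntimeWarning, stacklevel=2
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(products, [alpha / 2.0, 1.0 - alpha / 2.0])
    return IntervalResult(
        lower=float(lo),
        upper=float(hi),
        level=level,
        method="percentile_bootstrap",
        point_estimate=full.params.product(constraint.labels),
        n_boot_failures=n_failures,
    )


def monte_carlo_ci(
    fit: FitResult,
    constraint: ConstraintSpec | None = None,
    draws: int = 100_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> IntervalResult:
    """Monte Carlo CI for the indirect effect from a fitted full model.

    Coefficient vectors are drawn from the multivariate normal with mean
    equal to the MLEs of the constrained coefficients and covariance
    equal to their asymptotic (observed-information) covariance; the
    interval is formed from the quantiles of the products.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    constraint = _resolve_constraint(fit.model, constraint)
    mles = np.array([fit.params.betas[lab] for lab in constraint.labels])
    cov = coef_covariance(fit, constraint.labels)
    if not np.allclose(cov, cov.T):
        raise EstimationError("coefficient covariance is not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-12:
        raise EstimationError("coefficient covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    point = float(np.prod(mles))
    if np.all(cov == 0.0):  # degenerate: no sampling variability
        return IntervalResult(point, point, level, "monte_carlo", point)
    sample = rng.multivariate_normal(mles, cov, size=draws, method="svd")
    products = np.prod(sample, axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(products, [alpha / 2.0, 1.0 - alpha / 2.0])
    return IntervalResult(
        lower=float(lo), upper=float(hi), level=level, method="monte_carlo", point_estimate=point
    )


def profile_likelihood_ci(
    model: PathModel,
    data: pd.DataFrame | np.ndarray,
    constraint: ConstraintSpec | None = None,
    level: float = 0.95,
) -> IntervalResult:
    """Profile-likelihood CI for the indirect effect.

    The profile log-likelihood at c maximizes the model log-likelihood
    subject to product = c; endpoints solve
    -2 [ LL_prof(c) - LL_full ] = chi-square critical value, found by
    expanding a bracket outward from the MLE and bisecting (brentq).
    At the returned endpoints the equality holds to ``ENDPOINT_TOL``.
    """
    constraint = _resolve_constraint(model, constraint)
    suff = SuffStats.from_data(model, data)
    full = _fit_full_suff(model, suff)
    point = full.params.product(constraint.labels)
    crit = float(chi2.ppf(level, 1))

    try:
        sep = SeparableProfile(model, suff, constraint.labels)
    except ValueError:
        sep = None

    if sep is not None:
        t_mle = np.array([full.params.betas[lab] for lab in constraint.labels])

        def lrt_at(c: float) -> float:
            # starts derived from the full MLE only, so the value is a
            # deterministic function of c (root finding needs that)
            if c == point:
                return 0.0
            k = len(t_mle)
            starts = []
            p = float(np.prod(t_mle))
            if p != 0.0 and c != 0.0 and np.sign(p) == np.sign(c):
                starts.append(t_mle * (c / p) ** (1.0 / k))
            for j in range(k):  # move one coordinate onto the surface
                others = np.prod(np.delete(t_mle, j))
                if others != 0.0:
                    s = t_mle.copy()
                    s[j] = c / others
                    starts.append(s)
            base = abs(c) ** (1.0 / k)
            sign = np.ones(k)
            if c < 0:
                sign[0] = -1.0
            starts.append(base * sign if base > 0 else np.full(k, 0.1))
            t_opt, t_stat = sep.solve(c, starts)
            return max(0.0, t_stat)

    else:

        def lrt_at(c: float) -> float:
            if c == point:
                return 0.0
            null = _fit_null_suff(model, suff, constraint.with_constant(c))
            return max(0.0, -2.0 * (null.log_likelihood - full.log_likelihood))

    lower = _find_endpoint(lrt_at, point, crit, direction=-1.0)
    upper = _find_endpoint(lrt_at, point, crit, direction=+1.0)
    for endpoint in (lower, upper):
        gap = abs(lrt_at(endpoint) - crit)
        if gap > ENDPOINT_TOL:
            raise ConvergenceError(
                f"profile endpoint {endpoint:.6g} misses the critical value by {gap:.2e}"
            )
    return IntervalResult(
        lower=lower, upper=upper, level=level, method="profile_likelihood", point_estimate=point
    )


def _find_endpoint(lrt_at, point: float, crit: float, direction: float) -> float:
    """Bracket then bisect the root of T(c) - crit on one side of the MLE."""
    limit = 10.0 * abs(point) + 1.0
    step = 0.05 * (abs(point) + 0.1)
    prev_c, prev_t = point, 0.0
    c = point + direction * step
    while True:
        t = lrt_at(c)
        if t >= crit:
            break
        if t < prev_t - 1e-6:
            warnings.warn(
                "profile LRT decreased while moving away from the MLE "
                "(profile may be non-unimodal)",
                RuntimeWarning,
                stacklevel=3,
            )
        prev_c, prev_t = c, t
        step *= 2.0
        c = point + direction * (abs(c - point) + step)
        if abs(c - point) > limit:
            raise ConvergenceError(
                f"no profile bracket within {limit:.3g} of the estimate "
                f"(direction {direction:+.0f})"
            )
    lo, hi = (prev_c, c) if direction > 0 else (c, prev_c)
    return float(brentq(lambda x: lrt_at(x) - crit, lo, hi, xtol=1e-12, rtol=1e-14))
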