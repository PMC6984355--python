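"""Maximum-likelihood estimation of recursive path models, free and constrained.

Under multivariate-normal residuals the joint log-likelihood of a
recursive model factorizes over equations, so the *full* (unconstrained)
MLE is exact per-equation least squares with divisor-n residual
variances.  All estimation here runs on the sufficient statistics
(n, sample mean, divisor-n sample covariance), which makes a single fit
O(p^3) regardless of the number of rows.

The *null* model maximizes the same likelihood subject to the product
constraint g(beta) = b_1 b_2 ... b_k = c:

* ``c == 0``: the constraint set is the union of the hyperplanes
  {b_j = 0}; on each hyperplane the constrained MLE is again closed-form
  least squares with that coefficient removed, so the exact optimum is
  the best of the k branch fits (solver ``"branch"``).
* ``c != 0`` (profile-likelihood endpoints): all parameters other than
  the k constrained coefficients have closed-form optima given those
  coefficients, so SLSQP runs on the k-dimensional profiled problem
  (solver ``"reduced"``).
* ``"slsqp"``: a generic multi-start SLSQP over the full parameter
  vector (variances on the log scale); slower, used as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize

from .exceptions import (
    ConvergenceError,
    EstimationError,
    InputDataError,
    InternalConsistencyError,
)
from .path_model import (
    ConstraintSpec,
    ImpliedMoments,
    ParameterVector,
    PathModel,
    implied_moments,
)

__all__ = ["FitResult", "SuffStats", "fit_full", "fit_null", "log_likelihood", "coef_covariance"]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: |g(beta)| tolerance for a converged constrained fit
CONSTRAINT_TOL = 1e-8
#: slack allowed before LL_null > LL_full is treated as an internal error
NESTING_TOL = 1e-6


@dataclass(frozen=True)
class SuffStats:
    """Sufficient statistics of a data table: n, mean, divisor-n covariance."""

    n: int
    mean: np.ndarray
    cov: np.ndarray
    variables: tuple[str, ...]

    @classmethod
    def from_data(cls, model: PathModel, data: pd.DataFrame | np.ndarray) -> "SuffStats":
        arr = _validate_data(model, data)
        return cls.from_array(arr, model.variables)

    @classmethod
    def from_array(cls, arr: np.ndarray, variables: tuple[str, ...]) -> "SuffStats":
        n = arr.shape[0]
        mean = arr.mean(axis=0)
        centered = arr - mean
        cov = centered.T @ centered / n
        return cls(n=n, mean=mean, cov=cov, variables=variables)

    def index(self, names: Iterable[str]) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.variables)}
        return np.array([pos[v] for v in names], dtype=int)


@dataclass(frozen=True)
class FitResult:
    """MLE of a path model: parameter estimates, log-likelihood, diagnostics."""

    model: PathModel
    params: ParameterVector
    log_likelihood: float
    converged: bool
    n_obs: int
    constraint_violation: float = 0.0
    method: str = "closed_form"
    suff: SuffStats = field(repr=False, default=None)

    @property
    def implied(self) -> ImpliedMoments:
        return implied_moments(self.model, self.params)

    def indirect_effect(self, labels: Sequence[str] | None = None) -> float:
        """Product of the constrained coefficients (the indirect effect)."""
        if labels is None:
            if self.model.constraint is None:
                raise ValueError("model has no constraint; pass labels explicitly")
            labels = self.model.constraint.labels
        return self.params.product(labels)


def _validate_data(model: PathModel, data: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(data, np.ndarray):
        if data.ndim != 2 or data.shape[1] != len(model.variables):
            raise InputDataError(
                f"array data must be 2-D with {len(model.variables)} columns "
                "in model variable order"
            )
        arr = np.asarray(data, dtype=float)
    else:
        df = pd.DataFrame(data)
        missing = [v for v in model.variables if v not in df.columns]
        if missing:
            raise InputDataError(f"data lacks model variables {missing}")
        try:
            arr = df[list(model.variables)].to_numpy(dtype=float)
        except (TypeError, ValueError) as err:
            raise InputDataError(f"non-numeric data: {err}") from err
    if not np.isfinite(arr).all():
        raise InputDataError("data contains missing or non-finite values (not supported)")
    return arr


def _check_identifiable(model: PathModel, n: int) -> None:
    max_preds = max((len(model.predictors(v)) for v in model.variables), default=0)
    if n <= max_preds + 1:
        raise EstimationError(
            f"n={n} rows cannot identify an equation with "
            f"{max_preds} predictors plus intercept and residual variance"
        )


# ---------------------------------------------------------------------------
# closed-form estimation with (optionally) fixed coefficients
# ---------------------------------------------------------------------------


def _fit_equation(
    model: PathModel, suff: SuffStats, v: str, fixed: Mapping[str, float]
) -> tuple[np.ndarray, float, float]:
    """Per-equation MLE with some coefficients held fixed.

    Free coefficients given the fixed ones solve the normal equations of
    the partial regression of the adjusted response on the free
    predictors.  Returns (coefficients, intercept, ML residual variance).
    """
    m, S = suff.mean, suff.cov
    iv = suff.index([v])[0]
    terms = model.equations[v]
    ip = suff.index([pred for _, pred in terms])
    labs = [lab for lab, _ in terms]
    coefs = np.empty(len(terms))
    fixed_mask = np.array([lab in fixed for lab in labs], dtype=bool)
    coefs[fixed_mask] = [fixed[lab] for lab, is_f in zip(labs, fixed_mask) if is_f]
    free = ~fixed_mask
    if free.any():
        Sgg = S[np.ix_(ip[free], ip[free])]
        rhs = S[ip[free], iv]
        if fixed_mask.any():
            rhs = rhs - S[np.ix_(ip[free], ip[fixed_mask])] @ coefs[fixed_mask]
        try:
            coefs[free] = np.linalg.solve(Sgg, rhs)
        except np.linalg.LinAlgError as err:
            raise EstimationError(f"rank-deficient design in equation for {v!r}") from err
    # residual variance of v - coefs . preds at the ML intercept
    psi = float(
        S[iv, iv] - 2.0 * coefs @ S[ip, iv] + coefs @ S[np.ix_(ip, ip)] @ coefs
    )
    intercept = float(m[iv] - coefs @ m[ip])
    return coefs, intercept, psi


def _fit_with_fixed(
    model: PathModel, suff: SuffStats, fixed: Mapping[str, float]
) -> tuple[ParameterVector, float]:
    """Closed-form MLE with some path coefficients held at given values.

    Returns the assembled parameter vector and the joint log-likelihood
    (sum of the per-equation conditional-normal profile
    log-likelihoods; divisor-n variances).
    """
    n = suff.n
    betas: dict[str, float] = {}
    psis: dict[str, float] = {}
    ll = 0.0
    for v in model.variables:
        coefs, intercept, psi = _fit_equation(model, suff, v, fixed)
        if psi <= 0.0:
            raise EstimationError(
                f"degenerate fit: residual variance of {v!r} is {psi:.3e} <= 0"
            )
        if psi < 1e-10:
            warnings.warn(
                f"residual variance of {v!r} is {psi:.3e}, near the boundary",
                RuntimeWarning,
                stacklevel=3,
            )
        for (lab, _), val in zip(model.equations[v], coefs):
            betas[lab] = float(val)
        betas[model.intercept_label(v)] = intercept
        psis[model.variance_label(v)] = psi
        ll += -0.5 * n * (_LOG_2PI + np.log(psi) + 1.0)
    return ParameterVector(betas=betas, psis=psis), float(ll)


def fit_full(model: PathModel, data: pd.DataFrame | np.ndarray) -> FitResult:
    """Unconstrained MLE: exact per-equation least squares (divisor-n variances)."""
    suff = SuffStats.from_data(model, data)
    return _fit_full_suff(model, suff)


def _fit_full_suff(model: PathModel, suff: SuffStats) -> FitResult:
    _check_identifiable(model, suff.n)
    params, ll = _fit_with_fixed(model, suff, {})
    return FitResult(
        model=model,
        params=params,
        log_likelihood=ll,
        converged=True,
        n_obs=suff.n,
        method="closed_form",
        suff=suff,
    )


# ---------------------------------------------------------------------------
# log-likelihood at arbitrary parameter values
# ---------------------------------------------------------------------------


def log_likelihood(
    model: PathModel, params: ParameterVector, data: pd.DataFrame | np.ndarray
) -> float:
    """Exact multivariate-normal log-likelihood of the data at ``params``.

    Evaluated through the model-implied moments; equals the sum of the
    per-equation conditional-normal log-densities (the recursive
    factorization of the joint density).
    """
    suff = SuffStats.from_data(model, data)
    return _loglik_suff(model, params, suff)


def _loglik_suff(model: PathModel, params: ParameterVector, suff: SuffStats) -> float:
    mom = implied_moments(model, params)
    return _loglik_moments(mom.mean, mom.covariance, suff)


def _loglik_moments(mean: np.ndarray, cov: np.ndarray, suff: SuffStats) -> float:
    """MVN log-likelihood from sufficient statistics.

    sum_i log N(y_i | mu, Sigma) =
      -n/2 [ p log 2pi + log|Sigma| + tr(Sigma^-1 S_n) + d' Sigma^-1 d ],
    with S_n the divisor-n covariance and d = ybar - mu.
    """
    p = len(mean)
    try:
        chol = np.linalg.cholesky(cov)
        d = suff.mean - mean
        half = scipy.linalg.solve_triangular(chol, d, lower=True)
        whitened = scipy.linalg.solve_triangular(chol, suff.cov, lower=True)
        whitened = scipy.linalg.solve_triangular(chol, whitened.T, lower=True)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as err:
        raise EstimationError("implied covariance matrix is not positive definite") from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    quad = float(half @ half)
    tr = float(np.trace(whitened))
    return -0.5 * suff.n * (p * _LOG_2PI + logdet + tr + quad)


def _loglik_equations(
    model: PathModel, params: ParameterVector, data: pd.DataFrame | np.ndarray
) -> float:
    """Row-wise equation-by-equation log-likelihood (independent oracle route)."""
    arr = _validate_data(model, data)
    pos = {v: i for i, v in enumerate(model.variables)}
    ll = 0.0
    for v in model.variables:
        resid = arr[:, pos[v]] - params.betas[model.intercept_label(v)]
        for lab, pred in model.equations[v]:
            resid = resid - params.betas[lab] * arr[:, pos[pred]]
        psi = params.psis[model.variance_label(v)]
        if psi <= 0:
            raise EstimationError(f"non-positive variance for {v!r}")
        ll += float(-0.5 * np.sum(_LOG_2PI + np.log(psi) + resid**2 / psi))
    return ll


# ---------------------------------------------------------------------------
# constrained (null-model) estimation
# ---------------------------------------------------------------------------


def fit_null(
    model: PathModel,
    data: pd.DataFrame | np.ndarray,
    constraint: ConstraintSpec | None = None,
    solver: str = "auto",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """MLE subject to the product constraint g(beta) = c.

    ``solver="auto"`` picks the exact branch enumeration for c = 0 and
    the profiled SLSQP for c != 0; ``"slsqp"`` forces the generic
    multi-start optimizer over the full parameter vector.
    """
    constraint = _resolve_constraint(model, constraint)
    suff = SuffStats.from_data(model, data)
    return _fit_null_suff(model, suff, constraint, solver=solver, n_starts=n_starts, seed=seed)


def _resolve_constraint(model: PathModel, constraint: ConstraintSpec | None) -> ConstraintSpec:
    if constraint is None:
        constraint = model.constraint
    if constraint is None:
        raise ValueError("no constraint given and the model declares none")
    unknown = [lab for lab in constraint.labels if lab not in model.coefficient_labels]
    if unknown:
        raise ValueError(f"constraint labels {unknown} not in model")
    return constraint


def _fit_null_suff(
    model: PathModel,
    suff: SuffStats,
    constraint: ConstraintSpec,
    solver: str = "auto",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    _check_identifiable(model, suff.n)
    full = _fit_full_suff(model, suff)
    if solver == "auto":
        solver = "branch" if constraint.constant == 0.0 else "reduced"
    if solver == "branch":
        if constraint.constant != 0.0:
            raise ValueError("branch solver applies only to a zero constant")
        result = _fit_null_branch(model, suff, constraint)
    elif solver == "reduced":
        result = _fit_null_reduced(model, suff, constraint, full, n_starts, seed)
    elif solver == "slsqp":
        result = _fit_null_slsqp(model, suff, constraint, full, n_starts, seed)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if result.log_likelihood > full.log_likelihood + NESTING_TOL:
        raise InternalConsistencyError(
            f"null LL {result.log_likelihood:.6f} exceeds full LL "
            f"{full.log_likelihood:.6f}"
        )
    return result


def _fit_null_branch(
    model: PathModel, suff: SuffStats, constraint: ConstraintSpec
) -> FitResult:
    """Exact null fit for g(beta) = 0: best of the {b_j = 0} branch fits."""
    best: tuple[ParameterVector, float] | None = None
    for lab in constraint.labels:
        params, ll = _fit_with_fixed(model, suff, {lab: 0.0})
        if best is None or ll > best[1]:
            best = (params, ll)
    params, ll = best
    return FitResult(
        model=model,
        params=params,
        log_likelihood=ll,
        converged=True,
        n_obs=suff.n,
        constraint_violation=constraint.violation(params.betas),
        method="branch",
        suff=suff,
    )


def _profile_starts(
    labels: tuple[str, ...],
    constant: float,
    full: FitResult,
    n_starts: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Starting values on (or near) the constraint surface prod(t) = c."""
    k = len(labels)
    t_hat = np.array([full.params.betas[lab] for lab in labels])
    starts: list[np.ndarray] = []
    prod = float(np.prod(t_hat))
    if prod != 0.0 and np.sign(prod) == np.sign(constant):
        starts.append(t_hat * (constant / prod) ** (1.0 / k))
    # coordinate continuations: keep all but one coefficient at the MLE and
    # solve the remaining one from the constraint — the natural starts when
    # the constant is small relative to the MLE product
    for j in range(k):
        others = np.prod(np.delete(t_hat, j))
        if others != 0.0:
            t = t_hat.copy()
            t[j] = constant / others
            starts.append(t)
    # generic start: equal-magnitude coefficients matching the constant's sign
    base = float(np.abs(constant)) ** (1.0 / k)
    signs = np.ones(k)
    if constant < 0:
        signs[0] = -1.0
    starts.append(base * signs if base > 0 else np.full(k, 0.1))
    while len(starts) < n_starts:
        jitter = starts[0] * (1.0 + 0.3 * rng.standard_normal(k)) + 0.05 * rng.standard_normal(k)
        starts.append(jitter)
    return starts


def _project_to_constraint(t: np.ndarray, constant: float) -> np.ndarray:
    """Rescale t so that prod(t) == constant exactly (for c != 0)."""
    prod = float(np.prod(t))
    if prod == 0.0 or np.sign(prod) != np.sign(constant):
        return t
    return t * (constant / prod) ** (1.0 / len(t))


class SeparableProfile:
    """Fast profiled likelihood for a product constraint whose
    coefficients sit in distinct equations.

    There the profiled negative log-likelihood separates,
    -LL(t) = const + (n/2) sum_j log psi_j(t_j), with psi_j an exact
    quadratic in t_j: the residual variance of equation j after
    re-optimizing its free parameters, read off from evaluations at
    t_j in {0, 1, -1}.  SLSQP then runs on the k constrained
    coefficients only, with analytic gradients.
    """

    def __init__(self, model: PathModel, suff: SuffStats, labels: tuple[str, ...]):
        host: dict[str, str] = {}
        for v in model.variables:
            for lab, _ in model.equations[v]:
                if lab in labels:
                    host[lab] = v
        if len({host[lab] for lab in labels}) < len(labels):
            raise ValueError("constraint is not separable across equations")
        self.model, self.suff, self.labels = model, suff, labels
        self.half_n = 0.5 * suff.n
        qa, qb, q0, psi_hat, t_hat = [], [], [], [], []
        for lab in labels:
            v = host[lab]
            p0 = _fit_equation(model, suff, v, {lab: 0.0})[2]
            pp = _fit_equation(model, suff, v, {lab: 1.0})[2]
            pm = _fit_equation(model, suff, v, {lab: -1.0})[2]
            a = 0.5 * (pp + pm) - p0
            b = 0.5 * (pm - pp)  # psi(t) = a t^2 - b t + p0
            qa.append(a)
            qb.append(b)
            q0.append(p0)
            # unconstrained per-equation optimum of the quadratic
            t_free = b / (2.0 * a) if a > 0 else 0.0
            t_hat.append(t_free)
            psi_hat.append(a * t_free * t_free - b * t_free + p0)
        self.qa, self.qb, self.q0 = map(np.asarray, (qa, qb, q0))
        self.t_hat = np.asarray(t_hat)
        self.psi_hat = np.asarray(psi_hat)

    def psi(self, t: np.ndarray) -> np.ndarray:
        return self.qa * t * t - self.qb * t + self.q0

    def objective(self, t: np.ndarray) -> float:
        """(n/2) sum log psi_j(t_j), the t-dependent part of -LL."""
        psi = self.psi(t)
        if np.any(psi <= 0.0):
            return np.inf
        return self.half_n * float(np.sum(np.log(psi)))

    def gradient(self, t: np.ndarray) -> np.ndarray:
        return self.half_n * (2.0 * self.qa * t - self.qb) / self.psi(t)

    def lrt(self, t: np.ndarray) -> float:
        """T = -2 (LL(t) - LL_full) = n sum log(psi_j(t_j)/psi_hat_j)."""
        return 2.0 * (self.objective(t) - self.half_n * float(np.sum(np.log(self.psi_hat))))

    def _fallback_starts(self, constant: float) -> list[np.ndarray]:
        """Equal-magnitude starts over all sign patterns matching the constant."""
        k = len(self.labels)
        base = max(abs(constant), 1e-8) ** (1.0 / k)
        out = []
        for bits in range(2 ** (k - 1)):
            signs = np.ones(k)
            for j in range(k - 1):
                if (bits >> j) & 1:
                    signs[j] = -1.0
            # last sign makes the product sign match the constant
            target = np.sign(constant) if constant != 0 else 1.0
            signs[k - 1] = target * np.prod(signs[: k - 1])
            out.append(base * signs)
            out.append(0.5 * base * signs + 0.2 * signs)
        return out

    def solve(
        self, constant: float, starts: Iterable[np.ndarray]
    ) -> tuple[np.ndarray, float]:
        """Best constrained optimum over the given starts: (t, T)."""
        scale = 5.0 * (np.abs(self.t_hat) + 1.0)
        primary = [np.clip(x0, -scale, scale) for x0 in starts]
        best: tuple[np.ndarray, float] | None = None

        def consider(t: np.ndarray | None) -> None:
            nonlocal best
            if t is None:
                return
            val = self.objective(t)
            if np.isfinite(val) and (best is None or val < best[1]):
                best = (t, val)

        # Newton from every start (cheap); sign-pattern fallbacks keep the
        # tracked optimum on the globally best component of the surface
        pending: list[np.ndarray] = []
        for x0 in primary + self._fallback_starts(constant):
            t = self._newton(x0, constant)
            if t is None:
                pending.append(x0)
            else:
                consider(t)
        # starts where Newton stalled get the slower SLSQP treatment, but
        # only while they could still improve on the best optimum found
        for x0 in pending:
            if best is not None and self.objective(x0) > best[1] + 2.0:
                continue
            consider(self._slsqp_one(x0, constant))
        if best is None:
            raise ConvergenceError(
                f"no start converged for the profiled constraint g(beta)={constant}"
            )
        return best[0], self.lrt(best[0])

    def _slsqp_one(self, x0: np.ndarray, constant: float) -> np.ndarray | None:
        res = minimize(
            self.objective,
            x0,
            jac=self.gradient,
            method="SLSQP",
            constraints=[
                {
                    "type": "eq",
                    "fun": lambda t: np.prod(t) - constant,
                    "jac": lambda t: np.array(
                        [np.prod(np.delete(t, j)) for j in range(len(t))]
                    ),
                }
            ],
            options={"maxiter": 100, "ftol": 1e-12},
        )
        if not np.all(np.isfinite(res.x)):
            return None
        t = _project_to_constraint(res.x, constant) if constant != 0.0 else res.x
        polished = self._newton(t, constant)
        t = polished if polished is not None else t
        if abs(np.prod(t) - constant) > CONSTRAINT_TOL or not np.isfinite(self.objective(t)):
            return None
        return t

    def _newton(self, t0: np.ndarray, constant: float) -> np.ndarray | None:
        """Damped Newton on the KKT system of the profiled problem.

        Solves grad = lambda * constraint-gradient, prod(t) = constant,
        with analytic Jacobian, to ~machine precision; SLSQP alone
        leaves ~1e-4 jitter in the LRT along a profile trace, which the
        endpoint root-finding cannot tolerate.  Returns None unless the
        iteration settles on a feasible stationary point.
        """
        k = len(t0)
        qa, qb, q0 = self.qa.tolist(), self.qb.tolist(), self.q0.tolist()
        half_n = self.half_n
        tt = [float(v) for v in t0]
        if not all(np.isfinite(tt)):
            return None

        def psis(ts):
            return [a * t * t - b * t + p for a, b, p, t in zip(qa, qb, q0, ts)]

        def cgrads(ts):
            out = []
            for j in range(k):
                p = 1.0
                for m in range(k):
                    if m != j:
                        p *= ts[m]
                out.append(p)
            return out

        psi = psis(tt)
        if min(psi) <= 0.0:
            return None
        grad = [half_n * (2 * a * t - b) / p for a, b, t, p in zip(qa, qb, tt, psi)]
        cg = cgrads(tt)
        denom = sum(g * g for g in cg)
        lam = sum(g1 * g2 for g1, g2 in zip(grad, cg)) / denom if denom > 0 else 0.0
        def residual(ts, la):
            ps = psis(ts)
            if min(ps) <= 0.0 or not all(np.isfinite(ts)):
                return None, None, None
            cg_ = cgrads(ts)
            F_ = np.empty(k + 1)
            prod_t = 1.0
            for v in ts:
                prod_t *= v
            for j in range(k):
                F_[j] = half_n * (2 * qa[j] * ts[j] - qb[j]) / ps[j] - la * cg_[j]
            F_[k] = prod_t - constant
            return F_, ps, cg_

        converged = False
        J = np.zeros((k + 1, k + 1))
        F, psi, cg = residual(tt, lam)
        if F is None:
            return None
        for _ in range(60):
            maxF = float(np.max(np.abs(F)))
            if maxF < 1e-11:
                converged = True
                break
            for j in range(k):
                slope = 2 * qa[j] * tt[j] - qb[j]
                J[j, j] = half_n * (2 * qa[j] * psi[j] - slope * slope) / (psi[j] * psi[j])
                for m in range(k):
                    if m != j:
                        p = 1.0
                        for q in range(k):
                            if q != j and q != m:
                                p *= tt[q]
                        J[j, m] = -lam * p
                J[j, k] = -cg[j]
                J[k, j] = cg[j]
            try:
                step = np.linalg.solve(J, F)
            except np.linalg.LinAlgError:
                return None
            # backtracking on the residual norm guards narrow basins
            improved = False
            for scale in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
                tt_try = [tt[j] - scale * float(step[j]) for j in range(k)]
                lam_try = lam - scale * float(step[k])
                F_try, psi_try, cg_try = residual(tt_try, lam_try)
                if F_try is not None and float(np.max(np.abs(F_try))) < maxF:
                    tt, lam, F, psi, cg = tt_try, lam_try, F_try, psi_try, cg_try
                    improved = True
                    break
            if not improved:
                return None
        if not converged:
            return None
        t = np.array(tt)
        if abs(np.prod(t) - constant) > CONSTRAINT_TOL or not np.isfinite(self.objective(t)):
            return None
        return t


def _fit_null_reduced(
    model: PathModel,
    suff: SuffStats,
    constraint: ConstraintSpec,
    full: FitResult,
    n_starts: int,
    seed: int,
) -> FitResult:
    """SLSQP on the constrained coefficients with nuisance profiled in closed form."""
    labels = constraint.labels
    c = constraint.constant
    rng = np.random.default_rng(seed)
    starts = _profile_starts(labels, c, full, n_starts, rng)
    try:
        sep = SeparableProfile(model, suff, labels)
    except ValueError:
        sep = None
    if sep is not None:
        t, _ = sep.solve(c, starts)
    else:
        t = _solve_generic_reduced(model, suff, labels, c, starts)
    params, ll = _fit_with_fixed(model, suff, dict(zip(labels, t)))
    return FitResult(
        model=model,
        params=params,
        log_likelihood=ll,
        converged=True,
        n_obs=suff.n,
        constraint_violation=constraint.violation(params.betas),
        method="reduced_slsqp",
        suff=suff,
    )


def _solve_generic_reduced(
    model: PathModel,
    suff: SuffStats,
    labels: tuple[str, ...],
    c: float,
    starts: Iterable[np.ndarray],
) -> np.ndarray:
    def neg_profile_ll(t: np.ndarray) -> float:
        try:
            _, ll = _fit_with_fixed(model, suff, dict(zip(labels, t)))
        except EstimationError:
            return np.inf
        return -ll

    best: tuple[np.ndarray, float] | None = None
    diagnostics: list[str] = []
    for x0 in starts:
        res = minimize(
            neg_profile_ll,
            x0,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda t: np.prod(t) - c}],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if not res.success:
            diagnostics.append(str(res.message))
            continue
        t = _project_to_constraint(res.x, c) if c != 0.0 else res.x
        val = neg_profile_ll(t)
        if abs(np.prod(t) - c) > CONSTRAINT_TOL:
            diagnostics.append(f"constraint violation {abs(np.prod(t) - c):.2e}")
            continue
        if best is None or val < best[1]:
            best = (t, val)
    if best is None:
        raise ConvergenceError(
            f"no SLSQP start converged for g(beta)={c}; messages: {diagnostics}"
        )
    return best[0]


def _pack(model: PathModel, params: ParameterVector) -> tuple[np.ndarray, list[str], list[str]]:
    beta_names = [model.intercept_label(v) for v in model.variables] + list(
        model.coefficient_labels
    )
    psi_names = [model.variance_label(v) for v in model.variables]
    x = np.array(
        [params.betas[b] for b in beta_names] + [np.log(params.psis[s]) for s in psi_names]
    )
    return x, beta_names, psi_names


def _unpack(
    x: np.ndarray, beta_names: list[str], psi_names: list[str]
) -> ParameterVector:
    nb = len(beta_names)
    return ParameterVector(
        betas=dict(zip(beta_names, map(float, x[:nb]))),
        psis={s: float(np.exp(v)) for s, v in zip(psi_names, x[nb:])},
    )


def _fit_null_slsqp(
    model: PathModel,
    suff: SuffStats,
    constraint: ConstraintSpec,
    full: FitResult,
    n_starts: int,
    seed: int,
) -> FitResult:
    """Generic multi-start SLSQP over the full parameter vector.

    Residual variances are optimized on the log scale so positivity is
    built in.  Start 1 zeroes the smallest-|b| constrained coefficient
    of the full-model MLE (for c = 0) or rescales the constrained
    coefficients onto the surface (c != 0); further starts are jittered.
    """
    x_full, beta_names, psi_names = _pack(model, full.params)
    labels = constraint.labels
    c = constraint.constant
    lab_idx = np.array([beta_names.index(lab) for lab in labels])

    def neg_ll(x: np.ndarray) -> float:
        params = _unpack(x, beta_names, psi_names)
        try:
            return -_loglik_suff(model, params, suff)
        except EstimationError:
            return np.inf

    def g(x: np.ndarray) -> float:
        return float(np.prod(x[lab_idx]) - c)

    rng = np.random.default_rng(seed)
    starts = []
    x0 = x_full.copy()
    if c == 0.0:
        smallest = lab_idx[np.argmin(np.abs(x_full[lab_idx]))]
        x0[smallest] = 0.0
    else:
        x0[lab_idx] = _project_to_constraint(x_full[lab_idx], c)
    starts.append(x0)
    for _ in range(n_starts - 1):
        starts.append(x0 + 0.2 * rng.standard_normal(x0.shape))

    best = None
    diagnostics: list[str] = []
    for s in starts:
        res = minimize(
            neg_ll,
            s,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": g}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not (res.success and abs(g(res.x)) <= CONSTRAINT_TOL):
            diagnostics.append(f"{res.message} (|g|={abs(g(res.x)):.2e})")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError(f"no SLSQP start converged: {diagnostics}")
    params = _unpack(best.x, beta_names, psi_names)
    return FitResult(
        model=model,
        params=params,
        log_likelihood=float(-best.fun),
        converged=True,
        n_obs=suff.n,
        constraint_violation=constraint.violation(params.betas),
        method="slsqp",
        suff=suff,
    )


# ---------------------------------------------------------------------------
# asymptotic covariance of coefficient MLEs (for the Monte Carlo CI)
# ---------------------------------------------------------------------------


def coef_covariance(fit: FitResult, labels: Sequence[str]) -> np.ndarray:
    """Asymptotic covariance of the requested coefficient MLEs.

    From the observed information of the joint normal likelihood, which
    is block-diagonal across equations for a recursive model: within the
    equation for v, cov(b_hat) = psi_v (Z'Z)^{-1} with Z = [1, preds];
    coefficients from different equations are asymptotically
    uncorrelated.
    """
    model, suff = fit.model, fit.suff
    if suff is None:
        raise ValueError("fit carries no sufficient statistics")
    k = len(labels)
    out = np.zeros((k, k))
    for v in model.variables:
        terms = model.equations[v]
        eq_labels = [lab for lab, _ in terms]
        hits = [(i, eq_labels.index(lab)) for i, lab in enumerate(labels) if lab in eq_labels]
        if not hits:
            continue
        ip = suff.index([pred for _, pred in terms])
        n, m = suff.n, suff.mean
        ZtZ = np.empty((len(terms) + 1, len(terms) + 1))
        ZtZ[0, 0] = 1.0
        ZtZ[0, 1:] = m[ip]
        ZtZ[1:, 0] = m[ip]
        ZtZ[1:, 1:] = suff.cov[np.ix_(ip, ip)] + np.outer(m[ip], m[ip])
        ZtZ *= n
        psi = fit.params.psis[model.variance_label(v)]
        block = psi * np.linalg.inv(ZtZ)
        for i, ei in hits:
            for j, ej in hits:
                out[i, j] = block[1 + ei, 1 + ej]
    return out
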