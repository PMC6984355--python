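"""Synthetic data for the sequential two-mediator simulation study.

Data are generated from the recursive system in topological order: the
exogenous variable X is a standardized draw, and each endogenous
variable is the coefficient-weighted sum of its predictors plus a
standardized residual scaled so that every variable has unit implied
variance.  Residual (and X) shocks are either standard normal or
non-normal via the Fleishman cubic-polynomial transform

    e = a + b Z + c Z^2 + d Z^3,   Z ~ N(0, 1),  a = -c,

whose coefficients are solved so that e has mean 0, variance 1 and the
target marginal skewness and *excess* kurtosis (the Vale-Maurelli
approach; with mutually independent shocks no intermediate-correlation
matching is needed).  The study's "moderate" and "severe" conditions
target (skewness, excess kurtosis) = (2, 7) and (3, 21).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .exceptions import InfeasibleMomentsError, ModelSpecificationError
from .path_model import ParameterVector, PathModel, sequential_two_mediator, topological_order

__all__ = [
    "GenerationConfig",
    "ResidualDistribution",
    "fleishman_coefficients",
    "simulate_dataset",
    "standardized_residual_variances",
]


@dataclass(frozen=True)
class ResidualDistribution:
    """Marginal shock distribution: normal, or Fleishman with target moments.

    ``kurtosis`` is *excess* kurtosis (0 for the normal distribution).
    """

    kind: str = "normal"
    skewness: float = 0.0
    kurtosis: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "nonnormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "normal" and (self.skewness != 0.0 or self.kurtosis != 0.0):
            raise ValueError("normal distribution cannot carry moment targets")

    @classmethod
    def normal(cls) -> "ResidualDistribution":
        return cls("normal")

    @classmethod
    def nonnormal(cls, skewness: float, kurtosis: float) -> "ResidualDistribution":
        return cls("nonnormal", skewness, kurtosis)

    @property
    def label(self) -> str:
        if self.kind == "normal":
            return "normal"
        return f"nonnormal(skew={self.skewness:g},kurt={self.kurtosis:g})"


#: moderate and severe non-normality conditions of the study grid
MODERATE_NONNORMAL = ResidualDistribution.nonnormal(2.0, 7.0)
SEVERE_NONNORMAL = ResidualDistribution.nonnormal(3.0, 21.0)


def _fleishman_residuals(x: np.ndarray, skew: float, exkurt: float) -> np.ndarray:
    b, c, d = x
    return np.array(
        [
            b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0,
            2 * c * (b * b + 24 * b * d + 105 * d * d + 2) - skew,
            24
            * (
                b * d
                + c * c * (1 + b * b + 28 * b * d)
                + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
            )
            - exkurt,
        ]
    )


def fleishman_coefficients(skewness: float, kurtosis: float) -> tuple[float, float, float, float]:
    """Solve the Fleishman moment equations for (a, b, c, d), a = -c.

    ``kurtosis`` is excess kurtosis.  Raises
    :class:`InfeasibleMomentsError` (naming the residuals of the best
    attempt) if no solution with positive leading coefficient exists.
    """
    if skewness == 0.0 and kurtosis == 0.0:
        return (0.0, 1.0, 0.0, 0.0)
    best_resid = np.inf
    sign = 1.0 if skewness >= 0 else -1.0
    starts = [
        np.array([1.0, 0.1 * sign, 0.1]),
        np.array([1.0, skewness / 6.0, 0.01]),
        np.array([0.9, 0.2 * sign, 0.05]),
        np.array([0.7, 0.3 * sign, 0.1]),
        np.array([0.5, 0.5 * sign, 0.15]),
        np.array([0.4, 0.25 * sign, 0.15]),
    ]
    # the moment equations can have several real roots; keep those with a
    # positive linear coefficient and return the least-distorting one
    # (smallest c^2 + d^2), which matches the published Fleishman tables
    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = root(_fleishman_residuals, x0, args=(skewness, kurtosis), tol=1e-13)
        resid = float(np.max(np.abs(_fleishman_residuals(sol.x, skewness, kurtosis))))
        best_resid = min(best_resid, resid)
        if sol.success and resid < 1e-10 and sol.x[0] > 0:
            roots.append(sol.x)
    if not roots:
        raise InfeasibleMomentsError(
            f"no Fleishman solution for skewness={skewness}, excess kurtosis={kurtosis} "
            f"(best moment residual {best_resid:.3e})"
        )
    b, c, d = min(roots, key=lambda x: x[1] ** 2 + x[2] ** 2)
    return (float(-c), float(b), float(c), float(d))


def _draw_shocks(
    rng: np.random.Generator, size: tuple[int, int], dist: ResidualDistribution
) -> np.ndarray:
    z = rng.standard_normal(size)
    if dist.kind == "normal":
        return z
    a, b, c, d = fleishman_coefficients(dist.skewness, dist.kurtosis)
    return a + b * z + c * z * z + d * z**3


@dataclass(frozen=True)
class GenerationConfig:
    """One design cell of the simulation study.

    ``beta`` sets the three chain coefficients b1 = b2 = b3 (the study's
    manipulated effect size); ``overrides`` may free any other path
    (all default to 0, and X is standard normal).  Residual variances
    are computed so every variable has implied variance 1.

    ``nonnormal_mode`` selects where the Fleishman transform acts:
    ``"observed"`` (default) draws the observed variables jointly by
    the Vale-Maurelli method — univariate Fleishman transforms of
    correlated normals whose intermediate correlations are solved so
    the sample matches the model-implied covariance exactly in
    population; ``"residual"`` instead applies independent Fleishman
    transforms to X and the structural residuals.  The two coincide for
    normal shocks; the observed mode is how standard SEM simulation
    software realizes marginal non-normality.
    """

    beta: float
    n: int
    distribution: ResidualDistribution = field(default_factory=ResidualDistribution.normal)
    seed: int | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    nonnormal_mode: str = "observed"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.nonnormal_mode not in ("observed", "residual"):
            raise ValueError(f"unknown nonnormal_mode {self.nonnormal_mode!r}")

    def coefficients(self, model: PathModel) -> dict[str, float]:
        chain = model.constraint.labels if model.constraint is not None else ("b1", "b2", "b3")
        betas = {lab: 0.0 for lab in model.coefficient_labels}
        betas.update({lab: self.beta for lab in chain})
        unknown = [lab for lab in self.overrides if lab not in betas]
        if unknown:
            raise ModelSpecificationError(f"override labels {unknown} not in model")
        betas.update(self.overrides)
        return betas


def standardized_residual_variances(
    model: PathModel, coefficients: dict[str, float]
) -> dict[str, float]:
    """Residual variances giving every variable unit implied variance.

    Walks the model in topological order, accumulating the implied
    covariance among processed variables; the structural variance of
    each variable (coefficients' quadratic form in its predictors'
    covariance) must stay below 1, else the requested coefficients are
    too large for the standardized scale.
    """
    order = topological_order(model)
    pos = {v: i for i, v in enumerate(order)}
    sigma = np.zeros((len(order), len(order)))
    psis: dict[str, float] = {}
    for v in order:
        i = pos[v]
        terms = model.equations[v]
        coefs = np.array([coefficients[lab] for lab, _ in terms])
        ip = np.array([pos[pred] for _, pred in terms], dtype=int)
        structural = float(coefs @ sigma[np.ix_(ip, ip)] @ coefs) if len(terms) else 0.0
        psi = 1.0 - structural
        if psi <= 0.0:
            raise ModelSpecificationError(
                f"coefficients leave non-positive residual variance {psi:.3f} for {v!r}"
            )
        psis[model.variance_label(v)] = psi
        if len(terms):
            cross = sigma[ip, :] .T @ coefs  # cov(v, earlier vars)
            sigma[i, :] = cross
            sigma[:, i] = cross
        sigma[i, i] = 1.0
    return psis


def generation_parameters(model: PathModel, config: GenerationConfig) -> ParameterVector:
    """The population parameter vector a config describes (zero means)."""
    betas = config.coefficients(model)
    psis = standardized_residual_variances(model, betas)
    for v in model.variables:
        betas[model.intercept_label(v)] = 0.0
    return ParameterVector(betas=betas, psis=psis)


def _intermediate_correlation(
    r: float, b: float, c: float, d: float
) -> float:
    """Solve the Vale-Maurelli cubic for the pre-transform correlation.

    For two Fleishman variates with identical coefficients and normal
    correlation rho, the post-transform correlation is
    r = rho (b^2 + 6 b d + 9 d^2) + 2 c^2 rho^2 + 6 d^2 rho^3;
    invert for rho, picking the real root in [-1, 1].
    """
    if r == 0.0:
        return 0.0
    roots = np.roots([6 * d * d, 2 * c * c, b * b + 6 * b * d + 9 * d * d, -r])
    real = roots[np.abs(roots.imag) < 1e-9].real
    ok = real[(real >= -1.0) & (real <= 1.0)]
    if len(ok) == 0:
        raise InfeasibleMomentsError(
            f"no intermediate correlation reproduces target correlation {r:.4f}"
        )
    return float(ok[np.argmin(np.abs(ok - r))])


def _vale_maurelli_sample(
    rng: np.random.Generator,
    n: int,
    cov: np.ndarray,
    dist: ResidualDistribution,
) -> np.ndarray:
    """Joint draw with target covariance and Fleishman marginal moments."""
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    a, b, c, d = fleishman_coefficients(dist.skewness, dist.kurtosis)
    p = cov.shape[0]
    inter = np.eye(p)
    for i in range(p):
        for j in range(i):
            inter[i, j] = inter[j, i] = _intermediate_correlation(corr[i, j], b, c, d)
    try:
        chol = np.linalg.cholesky(inter)
    except np.linalg.LinAlgError as err:
        raise InfeasibleMomentsError(
            "intermediate correlation matrix is not positive definite"
        ) from err
    z = rng.standard_normal((n, p)) @ chol.T
    return (a + b * z + c * z * z + d * z**3) * sd


def simulate_dataset(
    model: PathModel | None = None,
    config: GenerationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one dataset from the (standardized) recursive system.

    Normal shocks (and the ``"residual"`` non-normal mode) propagate
    independent standardized shocks through the equations in
    topological order; the ``"observed"`` non-normal mode draws the
    variables jointly by the Vale-Maurelli method at the model-implied
    covariance.  Pass ``rng`` to draw from an existing stream;
    otherwise ``config.seed`` seeds a fresh one.
    """
    if model is None:
        model = sequential_two_mediator()
    if config is None:
        raise ValueError("config is required")
    params = generation_parameters(model, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.distribution.kind == "nonnormal" and config.nonnormal_mode == "observed":
        from .path_model import implied_moments

        cov = implied_moments(model, params).covariance
        out = _vale_maurelli_sample(rng, config.n, cov, config.distribution)
        return pd.DataFrame(out, columns=list(model.variables))
    shocks = _draw_shocks(rng, (config.n, len(model.variables)), config.distribution)
    order = topological_order(model)
    pos = {v: i for i, v in enumerate(model.variables)}
    out = np.empty((config.n, len(model.variables)))
    for v in order:
        i = pos[v]
        col = np.sqrt(params.psis[model.variance_label(v)]) * shocks[:, i]
        for lab, pred in model.equations[v]:
            col = col + params.betas[lab] * out[:, pos[pred]]
        out[:, i] = col
    return pd.DataFrame(out, columns=list(model.variables))
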