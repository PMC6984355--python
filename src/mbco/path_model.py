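"""Recursive linear path models over observed variables.

A :class:`PathModel` is an acyclic system of linear structural equations
among observed variables with independent (diagonal-covariance) residuals
— the "all-y" representation: every variable has an equation, exogenous
variables simply have no predictors, so their "intercept" is a free mean
and their "residual variance" is a free marginal variance.  This gives a
single code path for the model-implied mean vector and covariance matrix
over all p variables, which the null-model bootstrap transforms require.

Equations are written in a small text syntax, one per line::

    M1 ~ b1*X + b7*C
    M2 ~ b2*M1 + b4*X + b8*C
    Y  ~ b3*M2 + b5*M1 + b6*X + b9*C

with an optional scalar product constraint to test, ``b1*b2*b3 == 0``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Mapping, Sequence

import numpy as np
import yaml

from .exceptions import ModelSpecificationError

__all__ = [
    "ConstraintSpec",
    "ImpliedMoments",
    "ParameterVector",
    "PathModel",
    "implied_moments",
    "sequential_two_mediator",
    "topological_order",
]

_TERM_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*\*\s*([A-Za-z_]\w*)\s*$")
_CONSTRAINT_RE = re.compile(
    r"^\s*(?:test\s*:\s*)?([A-Za-z_]\w*(?:\s*\*\s*[A-Za-z_]\w*)*)\s*==\s*([-+0-9.eE]+)\s*$"
)


@dataclass(frozen=True)
class ConstraintSpec:
    """A scalar product constraint g(beta) = prod(labels) == constant.

    The product of path coefficients along a mediation chain is the
    indirect effect; testing it against 0 is the usual null hypothesis.
    """

    labels: tuple[str, ...]
    constant: float = 0.0

    def __post_init__(self) -> None:
        if not self.labels:
            raise ModelSpecificationError("constraint needs at least one coefficient label")

    def value(self, betas: Mapping[str, float]) -> float:
        """Evaluate g(beta) = product of the constrained coefficients."""
        return float(np.prod([betas[lab] for lab in self.labels]))

    def violation(self, betas: Mapping[str, float]) -> float:
        return abs(self.value(betas) - self.constant)

    def with_constant(self, constant: float) -> "ConstraintSpec":
        return ConstraintSpec(self.labels, float(constant))


@dataclass(frozen=True)
class ParameterVector:
    """Free parameters of a path model.

    ``betas`` holds intercepts (``alpha_<var>``; the mean for exogenous
    variables) and path coefficients by label; ``psis`` holds one
    variance per variable (residual variance for endogenous variables,
    marginal variance for exogenous ones), keyed ``psi_<var>``.
    """

    betas: dict[str, float]
    psis: dict[str, float]

    def product(self, labels: Sequence[str]) -> float:
        return float(np.prod([self.betas[lab] for lab in labels]))


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied mean vector and covariance matrix, in model variable order."""

    variables: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray


@dataclass(frozen=True)
class PathModel:
    """A recursive path model: variables, equations, optional constraint.

    ``equations`` maps each variable to an ordered tuple of
    ``(coefficient_label, predictor)`` pairs; variables with an empty
    tuple are exogenous.  Intercept and variance labels are derived
    (``alpha_<var>``, ``psi_<var>``) and not stored.
    """

    variables: tuple[str, ...]
    equations: dict[str, tuple[tuple[str, str], ...]]
    constraint: ConstraintSpec | None = None

    def __post_init__(self) -> None:
        seen_labels: set[str] = set()
        for var in self.variables:
            if var not in self.equations:
                raise ModelSpecificationError(f"variable {var!r} has no equation entry")
            for lab, pred in self.equations[var]:
                if pred not in self.variables:
                    raise ModelSpecificationError(
                        f"equation for {var!r} uses unknown predictor {pred!r}"
                    )
                if lab in seen_labels:
                    raise ModelSpecificationError(f"duplicate coefficient label {lab!r}")
                seen_labels.add(lab)
        # Acyclicity is checked eagerly; raises on cycles.
        topological_order(self)
        if self.constraint is not None:
            missing = [lab for lab in self.constraint.labels if lab not in seen_labels]
            if missing:
                raise ModelSpecificationError(
                    f"constraint references unknown coefficient labels {missing}"
                )

    # -- construction -------------------------------------------------

    @classmethod
    def from_strings(
        cls,
        equations: Sequence[str],
        constraint: str | ConstraintSpec | None = None,
    ) -> "PathModel":
        """Build a model from equation strings like ``"M1 ~ b1*X + b7*C"``."""
        eqs: dict[str, tuple[tuple[str, str], ...]] = {}
        order: list[str] = []

        def note(var: str) -> None:
            if var not in order:
                order.append(var)

        for line in equations:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "~" not in line:
                raise ModelSpecificationError(f"equation {line!r} lacks '~'")
            lhs, rhs = line.split("~", 1)
            lhs = lhs.strip()
            if not lhs.isidentifier():
                raise ModelSpecificationError(f"invalid variable name {lhs!r}")
            if lhs in eqs:
                raise ModelSpecificationError(f"variable {lhs!r} defined twice")
            note(lhs)
            terms: list[tuple[str, str]] = []
            for term in rhs.split("+"):
                m = _TERM_RE.match(term)
                if m is None:
                    raise ModelSpecificationError(
                        f"cannot parse term {term.strip()!r} (expected 'label*Var')"
                    )
                lab, pred = m.group(1), m.group(2)
                note(pred)
                terms.append((lab, pred))
            eqs[lhs] = tuple(terms)
        for var in order:  # predictors never assigned an equation are exogenous
            eqs.setdefault(var, ())
        spec = parse_constraint(constraint) if isinstance(constraint, str) else constraint
        return cls(variables=tuple(order), equations=eqs, constraint=spec)

    @classmethod
    def from_yaml(cls, text: str) -> "PathModel":
        """Build a model from a YAML document with ``equations`` and optional ``test`` keys."""
        doc = yaml.safe_load(text)
        if isinstance(doc, dict) and "model" in doc:
            doc = doc["model"]
        if not isinstance(doc, dict) or "equations" not in doc:
            raise ModelSpecificationError("YAML model needs an 'equations' list")
        return cls.from_strings(doc["equations"], constraint=doc.get("test"))

    # -- introspection ------------------------------------------------

    @property
    def exogenous_vars(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if not self.equations[v])

    @property
    def endogenous_vars(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if self.equations[v])

    @property
    def coefficient_labels(self) -> tuple[str, ...]:
        return tuple(lab for v in self.variables for lab, _ in self.equations[v])

    def intercept_label(self, var: str) -> str:
        return f"alpha_{var}"

    def variance_label(self, var: str) -> str:
        return f"psi_{var}"

    @property
    def n_free_parameters(self) -> int:
        # one intercept and one variance per variable, plus all path coefficients
        return 2 * len(self.variables) + len(self.coefficient_labels)

    def predictors(self, var: str) -> tuple[str, ...]:
        return tuple(pred for _, pred in self.equations[var])


def parse_constraint(text: str) -> ConstraintSpec:
    """Parse ``"b1*b2*b3 == 0"`` (optionally prefixed ``"test:"``)."""
    m = _CONSTRAINT_RE.match(text)
    if m is None:
        raise ModelSpecificationError(f"cannot parse constraint {text!r}")
    labels = tuple(lab.strip() for lab in m.group(1).split("*"))
    return ConstraintSpec(labels=labels, constant=float(m.group(2)))


def topological_order(model: PathModel) -> tuple[str, ...]:
    """Variable order in which every predictor precedes its dependents.

    Ties are broken by the declared variable order, so the result is
    deterministic.  Raises :class:`ModelSpecificationError` naming the
    offending variables if the predictor graph has a cycle.
    """
    rank = {v: i for i, v in enumerate(model.variables)}
    ts = TopologicalSorter({v: set(model.predictors(v)) for v in model.variables})
    try:
        ts.prepare()
    except CycleError as err:
        cycle = err.args[1] if len(err.args) > 1 else "?"
        raise ModelSpecificationError(f"predictor graph has a cycle: {cycle}") from err
    out: list[str] = []
    while ts.is_active():
        ready = sorted(ts.get_ready(), key=rank.__getitem__)
        out.extend(ready)
        ts.done(*ready)
    return tuple(out)


def _structural_matrices(
    model: PathModel, params: ParameterVector
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(B, alpha, psi) in declared variable order; y = alpha + B y + eps."""
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    B = np.zeros((p, p))
    alpha = np.empty(p)
    psi = np.empty(p)
    for v in model.variables:
        i = idx[v]
        alpha[i] = params.betas[model.intercept_label(v)]
        psi[i] = params.psis[model.variance_label(v)]
        for lab, pred in model.equations[v]:
            B[i, idx[pred]] = params.betas[lab]
    return B, alpha, psi


def implied_moments(model: PathModel, params: ParameterVector) -> ImpliedMoments:
    """Model-implied mean vector and covariance matrix.

    From the reduced form of the recursive system y = alpha + B y + eps:
    mu = (I - B)^{-1} alpha and Sigma = (I - B)^{-1} Psi (I - B)^{-T}
    with Psi = diag(psi).  (I - B) is always nonsingular for an acyclic
    model (it is triangular up to a permutation with unit diagonal).
    """
    B, alpha, psi = _structural_matrices(model, params)
    eye = np.eye(len(model.variables))
    # unit-diagonal triangular up to permutation => det +/- 1; assert, don't guard
    assert abs(abs(np.linalg.det(eye - B)) - 1.0) < 1e-8, "acyclic model yielded singular I-B"
    inv = np.linalg.inv(eye - B)
    mean = inv @ alpha
    cov = inv @ np.diag(psi) @ inv.T
    cov = (cov + cov.T) / 2.0
    return ImpliedMoments(variables=model.variables, mean=mean, covariance=cov)


def sequential_two_mediator(
    direct_paths: bool = False, covariate: bool = False
) -> PathModel:
    """The sequential two-mediator mediation model X -> M1 -> M2 -> Y.

    The default is the hypothesized mediation chain (b1: X->M1,
    b2: M1->M2, b3: M2->Y); the indirect effect of interest is
    b1*b2*b3.  ``direct_paths=True`` frees the direct paths as well
    (b4: X->M2, b5: M1->Y, b6: X->Y), and ``covariate=True`` adds a
    covariate C to every equation (labels b7-b9), giving the general
    form used in observational applications.
    """
    c1 = " + b7*C" if covariate else ""
    c2 = " + b8*C" if covariate else ""
    c3 = " + b9*C" if covariate else ""
    if direct_paths:
        eqs = [
            f"M1 ~ b1*X{c1}",
            f"M2 ~ b2*M1 + b4*X{c2}",
            f"Y ~ b3*M2 + b5*M1 + b6*X{c3}",
        ]
    else:
        eqs = [f"M1 ~ b1*X{c1}", f"M2 ~ b2*M1{c2}", f"Y ~ b3*M2{c3}"]
    return PathModel.from_strings(eqs, constraint="b1*b2*b3 == 0")
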