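"""Shared test helpers: parameter construction and statsmodels-based oracles."""

import numpy as np
import statsmodels.api as sm

from mbco import ParameterVector


def make_params(model, betas=None, psis=None):
    """A complete parameter vector: zero paths/intercepts, unit variances."""
    b = {lab: 0.0 for lab in model.coefficient_labels}
    b.update({model.intercept_label(v): 0.0 for v in model.variables})
    p = {model.variance_label(v): 1.0 for v in model.variables}
    if betas:
        b.update(betas)
    if psis:
        p.update(psis)
    return ParameterVector(betas=b, psis=p)


def ols_refit(model, data, drop_label=None):
    """statsmodels-based per-equation MLE (independent oracle route).

    Returns (betas, psis, loglik) with ML (divisor-n) residual variances;
    ``drop_label`` removes one path coefficient (fixes it at zero).
    """
    n = len(data)
    betas, psis, ll = {}, {}, 0.0
    for v in model.variables:
        terms = [(lab, pred) for lab, pred in model.equations[v] if lab != drop_label]
        if terms:
            X = sm.add_constant(data[[pred for _, pred in terms]].to_numpy())
            res = sm.OLS(data[v].to_numpy(), X).fit()
            betas[model.intercept_label(v)] = res.params[0]
            for (lab, _), val in zip(terms, res.params[1:]):
                betas[lab] = val
            psi = float(res.ssr / n)
        else:
            betas[model.intercept_label(v)] = float(data[v].mean())
            psi = float(data[v].var(ddof=0))
        if drop_label in [lab for lab, _ in model.equations[v]]:
            betas[drop_label] = 0.0
        psis[model.variance_label(v)] = psi
        ll += -0.5 * n * (np.log(2 * np.pi) + np.log(psi) + 1.0)
    return betas, psis, ll
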