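"""Propensity-score estimation by maximum-likelihood logistic regression.

The propensity score PS = Pr(Z = 1 | X) is fit by plain (unregularized) ML
logit. For simulated cohorts the default covariate set is X3..X10 — the
covariates affecting survival — even though treatment was generated from
X1..X7; this deliberate misspecification mirrors the common practice of
selecting PS covariates by their association with the outcome, and is part
of the study design rather than something to correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dgp import Cohort
from .errors import PSFitError

__all__ = ["DEFAULT_PS_COVARIATES", "PSFit", "fit_logit", "fit_ps"]

#: Covariates used in the PS model for simulated cohorts (outcome-affecting set).
DEFAULT_PS_COVARIATES = tuple(f"x{i}" for i in range(3, 11))

_MAXITER = 100
_TOL = 1e-8


@dataclass(frozen=True)
class PSFit:
    """A fitted propensity model: intercept-first coefficients and fitted scores."""

    coefficients: np.ndarray
    ps_hat: np.ndarray
    covariate_names: tuple[str, ...]


def fit_logit(X: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ML logit of z on [1, X]; returns (coefficients, fitted probabilities).

    Raises :class:`PSFitError` on single-class response, perfect separation,
    or non-convergence (with the optimizer diagnostics attached).
    """
    z = np.asarray(z)
    if z.min() == z.max():
        raise PSFitError("treatment indicator is single-class; cannot fit PS model")
    X = np.asarray(X, dtype=float)
    # constant columns are absorbed by the intercept; keeping them would make
    # the Hessian singular
    keep = np.ptp(X, axis=0) > 0
    design = sm.add_constant(X[:, keep], has_constant="add")
    try:
        res = sm.Logit(z, design).fit(
            method="newton", maxiter=_MAXITER, tol=_TOL, disp=0
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise PSFitError(f"PS model fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise PSFitError(
            "PS model did not converge",
            diagnostics=dict(res.mle_retvals),
        )
    ps = np.asarray(res.predict(design))
    coefs = np.zeros(X.shape[1] + 1)
    coefs[0] = res.params[0]
    coefs[1:][keep] = res.params[1:]
    return coefs, ps


def fit_ps(cohort: Cohort, covariates=DEFAULT_PS_COVARIATES) -> PSFit:
    """Fit the propensity model on a cohort.

    ``covariates`` names columns of the cohort covariate matrix ('x1'..'x10');
    an intercept is always included. The fit is deterministic given the input
    and invariant to row order.
    """
    names = tuple(covariates)
    X = cohort.covariate_matrix(list(names))
    coefs, ps = fit_logit(X, cohort.Z)
    return PSFit(coefficients=coefs, ps_hat=ps, covariate_names=names)
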