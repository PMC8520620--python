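"""Newton-Raphson fitting of (weighted) conditional logistic likelihoods.

The likelihood handled here has one term per case,

    l_i = eta_i0 - log sum_j w_ij exp(eta_ij),

where row 0 is the case period (or, for the permutation likelihood, the
observed value), ``eta_ij`` is the linear predictor of row j and ``w_ij`` a
fixed positive denominator weight entering as a log offset.  Frequency
multiplicities scale each case's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

__all__ = ["ClogitFit", "fit_conditional_logit"]

_SEPARATION_BOUND = 30.0  # |theta| beyond this is numerically a separated fit


@dataclass
class ClogitFit:
    theta: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    separated: bool


def _ll_grad_hess(theta, covs, mult, logw, want_hess=True):
    # covs: (n, R, p); logw: (n, R) with -inf padding for absent rows
    eta = covs @ theta + logw  # (n, R)
    lse = logsumexp(eta, axis=1)
    ll = float(np.sum(mult * ((covs[:, 0, :] @ theta) + logw[:, 0] - lse)))
    p = np.exp(eta - lse[:, None])  # (n, R)
    mean_cov = np.einsum("nr,nrp->np", p, covs)
    grad = np.einsum("n,np->p", mult, covs[:, 0, :] - mean_cov)
    if not want_hess:
        return ll, grad, None
    centered = covs - mean_cov[:, None, :]
    hess = -np.einsum("n,nr,nrp,nrq->pq", mult, p, centered, centered)
    return ll, grad, hess


def fit_conditional_logit(
    covariates: np.ndarray,
    multiplicity: np.ndarray,
    log_weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ClogitFit:
    """Maximise the conditional likelihood from theta = 0.

    Newton-Raphson with step-halving on likelihood decrease; if the Hessian
    is singular or the iteration stalls, falls back to BFGS on the analytic
    gradient.  A parameter wandering beyond a large bound is flagged as a
    separated (infinite) estimate.
    """
    covs = np.asarray(covariates, dtype=float)
    mult = np.asarray(multiplicity, dtype=float)
    n, R, p = covs.shape
    logw = (
        np.zeros((n, R)) if log_weights is None else np.asarray(log_weights, dtype=float)
    )
    theta = np.zeros(p)
    ll, grad, hess = _ll_grad_hess(theta, covs, mult, logw)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            res = optimize.minimize(
                lambda t: -_ll_grad_hess(t, covs, mult, logw, want_hess=False)[0],
                theta,
                jac=lambda t: -_ll_grad_hess(t, covs, mult, logw, want_hess=False)[1],
                method="BFGS",
                options={"gtol": 1e-10},
            )
            theta = res.x
            ll, grad, hess = _ll_grad_hess(theta, covs, mult, logw)
            converged = bool(res.success) and float(np.linalg.norm(res.jac, np.inf)) < 1e-6
            break
        # step-halving keeps the likelihood nondecreasing
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            ll_new, grad_new, hess_new = _ll_grad_hess(cand, covs, mult, logw)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        delta = float(np.max(np.abs(cand - theta)))
        theta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(theta)) > _SEPARATION_BOUND:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    cov = None
    if not separated:
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = None
    return ClogitFit(
        theta=theta,
        cov=cov,
        loglik=ll,
        converged=converged and not separated,
        n_iter=it,
        separated=separated,
    )
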