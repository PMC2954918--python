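"""Newton–Raphson maximum-likelihood logistic regression engine.

This is the numerical core every selection and validation loop sits on; it
is deliberately minimal (dense design matrix, Newton with step-halving,
observed-information covariance) so that a bootstrap run costing tens of
thousands of fits stays fast.  Convergence failures — typically complete or
quasi-complete separation in small resamples — are reported through the
``converged`` flag, never by silently returning garbage.
"""

from __future__ import annotations

import numpy as np

_MAX_ITER = 60
_TOL = 1e-10
# |linear predictor| beyond which fitted probabilities are numerically 0/1;
# used as a quasi-separation heuristic when Newton keeps inflating betas.
_ETA_DIVERGED = 30.0


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_irls(X: np.ndarray, y: np.ndarray):
    """Fit a logistic model by Newton's method with step-halving.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) 0/1 outcomes.

    Returns
    -------
    beta : (p,) ML estimates.
    loglik : float, maximised log-likelihood.
    cov : (p, p) inverse observed information (NaN-filled if singular).
    converged : bool.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = np.zeros(n)
    ll = _loglik(eta, y)
    converged = False
    for _ in range(_MAX_ITER):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # singular information: ridge-stabilise once, else give up
            H_r = H + 1e-8 * np.eye(p) * max(1.0, np.trace(H) / p)
            try:
                step = np.linalg.solve(H_r, grad)
            except np.linalg.LinAlgError:
                break
        # step-halving line search on the log-likelihood
        scale = 1.0
        for _half in range(25):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        improved = ll_c - ll
        beta, eta, ll = cand, eta_c, ll_c
        if improved < _TOL * (abs(ll) + 1.0):
            # flag quasi-separation: likelihood flat but fit is degenerate
            if np.max(np.abs(eta)) > _ETA_DIVERGED and np.max(np.abs(grad)) > 1e-3:
                converged = False
            else:
                converged = True
            break
    if converged and np.max(np.abs(eta)) > 4 * _ETA_DIVERGED:
        converged = False  # estimates ran off to +/- infinity
    if converged and p > 1:
        mu_chk = 1.0 / (1.0 + np.exp(-eta))
        if np.all((mu_chk < 1e-10) | (mu_chk > 1 - 1e-10)):
            converged = False  # perfect separation: every fitted prob is 0/1
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, ll, cov, converged


def null_fit(y: np.ndarray):
    """Closed-form intercept-only fit: logit of the event fraction."""
    n = y.size
    k = float(np.sum(y))
    if k == 0 or k == n:
        # degenerate one-class data; caller decides whether this is an error
        pbar = np.clip(k / n, 1e-12, 1 - 1e-12)
        ll = k * np.log(pbar) + (n - k) * np.log(1 - pbar)
        return float(np.log(pbar / (1 - pbar))), float(ll)
    pbar = k / n
    ll = k * np.log(pbar) + (n - k) * np.log(1 - pbar)
    return float(np.log(pbar / (1 - pbar))), float(ll)
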