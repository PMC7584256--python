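"""Random-intercept logistic regression via adaptive Gauss-Hermite quadrature.

For a binary level-1 response with one random intercept per group, the
marginal likelihood is a product over groups of one-dimensional integrals

    L_j = int phi(u; 0, s2) prod_i Bernoulli(y_ij | expit(x_ij' b + u)) du.

Each integral is approximated by adaptive GHQ: the integrand's mode and
curvature are found per group by Newton's method, the Hermite nodes are
recentered and rescaled accordingly, and the log-likelihood is maximized over
(b, log s) with BFGS. The mode search is vectorized across groups, so one
objective evaluation is O(N + J * nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .exceptions import ConvergenceError


@dataclass
class LogisticGLMMFit:
    beta: np.ndarray
    sigma2_b: float
    blups: np.ndarray
    linear_predictor: np.ndarray  # X beta + blup[group]
    loglike: float
    converged: bool
    boundary: bool


def _group_modes(eta, y, group_codes, n_groups, sigma2, n_iter=30, tol=1e-10):
    """Newton mode search of h_j(u) = sum_i log p(y_ij | eta_ij + u) - u^2/(2 s2)."""
    u = np.zeros(n_groups)
    for _ in range(n_iter):
        p = expit(eta + u[group_codes])
        g = np.bincount(group_codes, weights=y - p, minlength=n_groups) - u / sigma2
        w = np.bincount(group_codes, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        step = g / w
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    h2 = np.bincount(group_codes, weights=(lambda p: p * (1 - p))(expit(eta + u[group_codes])),
                     minlength=n_groups) + 1.0 / sigma2
    return u, h2


def _neg_loglike(params, X, y, group_codes, n_groups, z, w):
    beta, s = params[:-1], params[-1]
    sigma2 = np.exp(2 * s)
    eta = X @ beta
    u_hat, h2 = _group_modes(eta, y, group_codes, n_groups, sigma2)
    tau = 1.0 / np.sqrt(h2)
    # adaptive nodes u_q = u_hat + sqrt(2) tau z_q  (per group x node)
    nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    # per (group, node) Bernoulli log-likelihood sums
    ll = np.zeros((n_groups, z.size))
    for q in range(z.size):
        e = eta + nodes[group_codes, q]
        ll[:, q] = np.bincount(group_codes, weights=y * log_expit(e) + (1 - y) * log_expit(-e),
                               minlength=n_groups)
    log_int = ll - 0.5 * nodes**2 / sigma2 + z[None, :] ** 2 + np.log(w)[None, :]
    m = log_int.max(axis=1)
    lse = m + np.log(np.sum(np.exp(log_int - m[:, None]), axis=1))
    logL = np.sum(lse + np.log(np.sqrt(2.0) * tau) - 0.5 * np.log(2 * np.pi * sigma2))
    return -logL


def fit_logistic_glmm(y, X, group_codes, n_groups, n_nodes: int = 15) -> LogisticGLMMFit:
    """Maximum likelihood for the random-intercept logistic model (AGHQ)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if set(np.unique(y).tolist()) - {0.0, 1.0}:
        raise ConvergenceError("logistic GLMM requires a 0/1 response")
    if np.ptp(y) == 0:
        raise ConvergenceError("logistic response is constant; model is degenerate (separation)")
    z, w = np.polynomial.hermite.hermgauss(n_nodes)

    # pooled logistic start values via a few IRLS steps
    beta0 = np.zeros(X.shape[1])
    for _ in range(25):
        p = expit(X @ beta0)
        W = np.maximum(p * (1 - p), 1e-10)
        try:
            delta = np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - p))
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"logistic start values failed: {e}") from e
        beta0 = beta0 + delta
        if np.max(np.abs(delta)) < 1e-8:
            break
    if np.max(np.abs(beta0)) > 30:
        raise ConvergenceError("separation detected in logistic fit (diverging coefficients)")

    x0 = np.concatenate([beta0, [np.log(0.7)]])
    res = minimize(
        _neg_loglike, x0, args=(X, y, group_codes, n_groups, z, w),
        method="BFGS", options={"gtol": 1e-6, "maxiter": 200},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("logistic GLMM quadrature failed (non-finite likelihood)")
    beta, s = res.x[:-1], res.x[-1]
    sigma2 = float(np.exp(2 * s))
    boundary = sigma2 < 1e-6
    u_hat, _ = _group_modes(X @ beta, y, group_codes, n_groups, max(sigma2, 1e-10))
    return LogisticGLMMFit(
        beta=beta,
        sigma2_b=0.0 if boundary else sigma2,
        blups=u_hat if not boundary else np.zeros(n_groups),
        linear_predictor=X @ beta + (u_hat if not boundary else np.zeros(n_groups))[group_codes],
        loglike=-float(res.fun),
        converged=bool(res.success or res.status == 2),  # status 2: precision loss near optimum
        boundary=bool(boundary),
    )
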