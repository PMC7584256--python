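"""Random-intercept linear mixed model via profiled REML.

The model is y = X b + Z u + e with a single random intercept per group,
u_j ~ N(0, s2_b), e ~ N(0, s2_e). With lam = s2_b / s2_e the marginal
covariance of group j is s2_e (I + lam J), whose inverse and determinant are
closed-form (Woodbury), so beta and s2_e profile out and REML reduces to a
one-dimensional search over lam. All per-group quantities enter only through
group sums, so one criterion evaluation costs O(J p^2 + p^3).

This solver is the workhorse behind the mediator and outcome mixed models; it
is cross-checked against statsmodels.MixedLM (REML) in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import qr
from scipy.optimize import minimize_scalar

from .exceptions import RankDeficiencyError, ValidationError

BOUNDARY_LAMBDA = 1e-8


@dataclass
class RandomInterceptFit:
    """REML fit of a random-intercept linear mixed model."""

    beta: np.ndarray
    se: np.ndarray
    sigma2_e: float
    sigma2_b: float
    lam: float
    blups: np.ndarray            # predicted random intercept per group
    linear_predictor: np.ndarray  # X beta + blup[group], per record
    boundary: bool                # variance estimate hit the zero boundary
    colnames: Optional[Sequence[str]] = None
    reml_criterion: float = np.nan

    @property
    def cov_beta(self):
        return self._cov

    def __post_init__(self):
        self._cov = None


def _check_rank(X: np.ndarray, colnames):
    _, R, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = np.sort(piv[np.flatnonzero(d < tol)])
    if bad.size:
        names = [colnames[i] for i in bad] if colnames is not None else list(bad)
        raise RankDeficiencyError(names)


def fit_random_intercept_lm(
    y: np.ndarray,
    X: np.ndarray,
    group_codes: np.ndarray,
    n_groups: int,
    colnames: Optional[Sequence[str]] = None,
) -> RandomInterceptFit:
    """Fit by REML with the variance ratio profiled out.

    ``group_codes`` must be 0-based and sorted so groups are contiguous (any
    order works for the sums, contiguity is not actually required).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    N, p = X.shape
    if N <= p:
        raise ValidationError(f"need more records ({N}) than fixed-effect columns ({p})")
    if np.ptp(y) == 0:
        raise ValidationError("response has zero variance")
    _check_rank(X, colnames)

    n_j = np.bincount(group_codes, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # group sums of columns of X and of y
    S = np.zeros((n_groups, p))
    for c in range(p):
        S[:, c] = np.bincount(group_codes, weights=X[:, c], minlength=n_groups)
    t = np.bincount(group_codes, weights=y, minlength=n_groups)

    def pieces(lam):
        c = lam / (1.0 + lam * n_j)
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        beta = np.linalg.solve(A, b)
        Q = yty - float(np.sum(c * t * t)) - float(b @ beta)
        return A, beta, Q, c

    def criterion(lam):
        A, _, Q, _ = pieces(lam)
        if Q <= 0:
            return np.inf
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (N - p) * np.log(Q) + float(np.sum(np.log1p(lam * n_j))) + logdetA

    # coarse grid on log-lambda, then a bounded 1-D refinement
    grid = np.concatenate([[0.0], np.exp(np.linspace(np.log(1e-6), np.log(1e3), 40))])
    vals = np.array([criterion(l) for l in grid])
    k = int(np.argmin(vals))
    if k == 0:
        lam_hat, crit = 0.0, vals[0]
    else:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda s: criterion(np.exp(s)),
            bounds=(np.log(max(lo, 1e-12)), np.log(max(hi, 1e-11))),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam_hat, crit = float(np.exp(res.x)), float(res.fun)
        if vals[k] < crit:
            lam_hat, crit = grid[k], vals[k]
        if criterion(0.0) <= crit:
            lam_hat, crit = 0.0, criterion(0.0)

    A, beta, Q, c = pieces(lam_hat)
    sigma2_e = Q / (N - p)
    boundary = lam_hat <= BOUNDARY_LAMBDA
    sigma2_b = 0.0 if boundary else lam_hat * sigma2_e
    blups = c * (t - S @ beta) if not boundary else np.zeros(n_groups)
    cov = sigma2_e * np.linalg.inv(A)
    fit = RandomInterceptFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma2_e=float(sigma2_e),
        sigma2_b=float(sigma2_b),
        lam=float(0.0 if boundary else lam_hat),
        blups=blups,
        linear_predictor=X @ beta + blups[group_codes],
        boundary=bool(boundary),
        colnames=list(colnames) if colnames is not None else None,
        reml_criterion=float(crit),
    )
    fit._cov = cov
    return fit
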