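"""Logistic mixed model with a random intercept, fitted by adaptive
Gauss-Hermite quadrature.

Binary markers are modeled as ``logit P(Y_ij = 1 | b_i) = x_ij' beta + b_i``
with ``b_i ~ N(0, sigma_b^2)``. The marginal likelihood integrates the
random intercept out with adaptive Gauss-Hermite quadrature (nodes centered
at each subject's posterior mode, scaled by the posterior curvature), and
individual predictions use the posterior mode of ``b_i`` — the non-gaussian
analogue of the BLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["GLMMFit", "fit_logistic_glmm", "posterior_mode"]


@dataclass
class GLMMFit:
    beta: np.ndarray
    sigma_b: float
    loglik: float
    converged: bool
    n_subjects: int
    n_obs: int

    @property
    def cov_re(self) -> np.ndarray:
        return np.array([[self.sigma_b ** 2]])


def _pad_by_subject(y, X, groups):
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    uniq, starts, counts = np.unique(groups, return_index=True, return_counts=True)
    m, ni_max = len(uniq), counts.max()
    Y = np.zeros((m, ni_max))
    ETA0 = np.zeros((m, ni_max, X.shape[1]))
    mask = np.zeros((m, ni_max), dtype=bool)
    for i, (s, c) in enumerate(zip(starts, counts)):
        Y[i, :c] = y[s:s + c]
        ETA0[i, :c] = X[s:s + c]
        mask[i, :c] = True
    return Y, ETA0, mask


def _modes(eta0, Y, mask, sigma_b, b0=None, n_iter=30):
    """Per-subject posterior mode of b via Newton, vectorized over subjects."""
    b = np.zeros(Y.shape[0]) if b0 is None else b0.copy()
    for _ in range(n_iter):
        p = expit(eta0 + b[:, None]) * mask
        g = ((Y - p) * mask).sum(1) - b / sigma_b ** 2
        h = -(p * (1 - p)).sum(1) - 1.0 / sigma_b ** 2
        step = g / h
        b = b - np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return b, -h  # mode and negative Hessian (precision)


def _negloglik(params, Y, Xpad, mask, nodes, weights):
    p_fix = Xpad.shape[2]
    beta = params[:p_fix]
    sigma_b = np.exp(params[p_fix])
    eta0 = Xpad @ beta
    bhat, prec = _modes(eta0, Y, mask, sigma_b)
    s = 1.0 / np.sqrt(prec)
    # adaptive GH: b = bhat + sqrt(2) s x_h
    total = 0.0
    log_terms = np.empty((Y.shape[0], nodes.size))
    for h, (xh, wh) in enumerate(zip(nodes, weights)):
        b = bhat + np.sqrt(2.0) * s * xh
        eta = eta0 + b[:, None]
        ll_y = np.where(mask, Y * eta - np.logaddexp(0.0, eta), 0.0).sum(1)
        log_phi = -0.5 * np.log(2 * np.pi) - np.log(sigma_b) - 0.5 * (b / sigma_b) ** 2
        log_terms[:, h] = np.log(wh) + xh ** 2 + ll_y + log_phi
    mx = log_terms.max(1, keepdims=True)
    li = mx[:, 0] + np.log(np.exp(log_terms - mx).sum(1)) \
        + 0.5 * np.log(2.0) + np.log(s)
    total = li.sum()
    return -total if np.isfinite(total) else 1e12


def fit_logistic_glmm(y, X, groups, n_nodes: int = 15) -> GLMMFit:
    """Fit the logistic random-intercept model by adaptive GH maximum
    likelihood (``n_nodes`` quadrature nodes, default 15)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary marker values must be 0/1")
    Y, Xpad, mask = _pad_by_subject(y, X, groups)
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    nodes, weights = hermgauss(n_nodes)

    # start: pooled logistic fit, moderate sigma_b
    from sklearn.linear_model import LogisticRegression

    if y.min() == y.max():
        beta0 = np.zeros(X.shape[1])
    else:
        lr = LogisticRegression(C=1e8, max_iter=200, fit_intercept=False)
        lr.fit(X, y)
        beta0 = lr.coef_.ravel()
    x0 = np.concatenate([beta0, [np.log(1.0)]])
    res = minimize(
        _negloglik, x0, args=(Y, Xpad, mask, nodes, weights),
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(np.log(1e-3), np.log(50.0))],
        options={"maxiter": 300},
    )
    beta = res.x[: X.shape[1]]
    return GLMMFit(
        beta=beta, sigma_b=float(np.exp(res.x[X.shape[1]])),
        loglik=-float(res.fun), converged=bool(res.success),
        n_subjects=Y.shape[0], n_obs=int(mask.sum()),
    )


def posterior_mode(fit: GLMMFit, y, X) -> np.ndarray:
    """Posterior mode of one subject's random intercept given their history
    (argmax of f(y | b) f(b)); empty history returns the prior mean 0."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        return np.zeros(1)
    X = np.atleast_2d(X)
    eta0 = (X @ fit.beta)[None, :]
    Y = y[None, :]
    mask = np.ones_like(Y, dtype=bool)
    b, _ = _modes(eta0, Y, mask, fit.sigma_b)
    return b
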