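"""Deviance-residual sparse partial least squares for survival (sPLS-DR).

Right-censored outcomes are first turned into a continuous surrogate: the
deviance residuals of the null model, a normalized transform of the
martingale residuals ``M_i = delta_i - Lambda_hat(T_i)`` built from the
marginal Nelson-Aalen cumulative hazard. Sparse PLS components are then
extracted to maximize covariance between the (standardized) predictors and
those residuals, with per-component lasso-style soft-thresholding of the
loadings, and a Cox model is fitted on the component scores. The number of
components (and optionally the threshold) is tuned by internal
cross-validation of the partial-likelihood deviance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .base import RegressionSurvivalLearner, breslow_loglik, nelson_aalen

__all__ = ["deviance_residuals", "SPLSDRLearner"]

THRESHOLD_GRID = (0.0, 0.25, 0.5, 0.75, 0.9)


def deviance_residuals(times, events, cumhaz=None) -> np.ndarray:
    """Deviance residuals of the null survival model.

    ``d_i = sign(M_i) * sqrt(-2 [M_i + delta_i log(delta_i - M_i)])`` with
    ``M_i = delta_i - Lambda_hat(T_i)`` and the convention
    ``delta_i log(delta_i - M_i) = 0`` when ``delta_i = 0``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if cumhaz is None:
        cumhaz = nelson_aalen(times, events.astype(int))
    lam = np.atleast_1d(cumhaz.at(times))
    M = events - lam
    if np.any((events == 1) & (M >= events)):
        raise ValueError("martingale residual >= event indicator: "
                         "zero cumulative hazard at an event time")
    logterm = np.where(events == 1, np.log(np.clip(events - M, 1e-300, None)), 0.0)
    inner = -2.0 * (M + events * logterm)
    return np.sign(M) * np.sqrt(np.clip(inner, 0.0, None))


def _soft_threshold(w, frac):
    if frac <= 0:
        return w.copy()
    lam = frac * np.max(np.abs(w))
    return np.sign(w) * np.clip(np.abs(w) - lam, 0.0, None)


def _spls_fit(Xs, y, n_comp, thr_frac=0.0, max_sparse=False):
    """Sparse PLS1: returns loadings W (p, C) and x-loadings P (p, C)."""
    Xc = Xs.copy()
    yc = y.astype(float).copy()
    p = Xs.shape[1]
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    for c in range(n_comp):
        w = Xc.T @ yc
        if np.allclose(w, 0):
            W, P = W[:, :c], P[:, :c]
            break
        if max_sparse:
            keep = np.argmax(np.abs(w))
            w_new = np.zeros_like(w)
            w_new[keep] = w[keep]
            w = w_new
        else:
            w = _soft_threshold(w, thr_frac)
            if np.allclose(w, 0):  # threshold removed everything: keep argmax
                keep = np.argmax(np.abs(Xc.T @ yc))
                w = np.zeros(p)
                w[keep] = (Xc.T @ yc)[keep]
        w = w / np.linalg.norm(w)
        t = Xc @ w
        tt = t @ t
        if tt <= 1e-12:
            W, P = W[:, :c], P[:, :c]
            break
        pl = Xc.T @ t / tt
        Xc = Xc - np.outer(t, pl)
        yc = yc - t * (yc @ t) / tt
        W[:, c], P[:, c] = w, pl
    return W, P


def _rotation(W, P):
    """W* = W (P'W)^{-1}: maps original standardized X to component scores."""
    return W @ np.linalg.pinv(P.T @ W)


class SPLSDRLearner(RegressionSurvivalLearner):
    """sPLS-DR survival learner.

    ``sparsity``: ``"none"`` (plain PLS loadings), ``"max"`` (one nonzero
    loading per component) or ``"optimize"`` (threshold fraction tuned over a
    grid jointly with the number of components).
    """

    def __init__(self, sparsity: str = "none", max_components: int = 10,
                 n_folds: int = 10, seed: int = 0):
        if sparsity not in ("none", "max", "optimize"):
            raise ValueError(f"unknown sparsity {sparsity!r}")
        self.sparsity = sparsity
        self.max_components = max_components
        self.n_folds = n_folds
        self.seed = seed
        self.name = f"spls_{'nosparse' if sparsity == 'none' else ('maxsparse' if sparsity == 'max' else 'optimize')}"

    def _component_scores(self, Xs, W, P):
        return Xs @ _rotation(W, P)

    def _cv_score(self, Xs, times, events, folds, n_comp, thr, max_sparse):
        dev = 0.0
        for k in range(self.n_folds):
            tr = folds != k
            dr = deviance_residuals(times[tr], events[tr])
            W, P = _spls_fit(Xs[tr], dr, n_comp, thr, max_sparse)
            if W.shape[1] == 0:
                return np.inf
            scores_tr = self._component_scores(Xs[tr], W, P)
            y_tr = Surv.from_arrays(events[tr].astype(bool), times[tr])
            cox = CoxPHSurvivalAnalysis(ties="breslow", alpha=1e-8)
            cox.fit(scores_tr, y_tr)
            lp = self._component_scores(Xs, W, P) @ cox.coef_
            dev += -2 * (breslow_loglik(lp, times, events)
                         - breslow_loglik(lp[tr], times[tr], events[tr]))
        return dev

    def fit(self, X: pd.DataFrame, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        self.feature_names_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        sd = Xv.std(0)
        drop = sd == 0
        if drop.any():
            warnings.warn(
                f"dropping {int(drop.sum())} zero-variance predictors from sPLS-DR",
                RuntimeWarning)
            self.feature_names_ = [c for c, d in zip(self.feature_names_, drop) if not d]
            Xv = Xv[:, ~drop]
            sd = sd[~drop]
        self.center_ = Xv.mean(0)
        self.scale_ = sd
        Xs = (Xv - self.center_) / self.scale_

        rng = np.random.default_rng(self.seed)
        folds = rng.permutation(len(times)) % self.n_folds
        max_c = min(self.max_components, Xs.shape[1])
        thr_grid = ((0.0,) if self.sparsity == "none"
                    else (0.0,) if self.sparsity == "max"
                    else THRESHOLD_GRID)
        max_sparse = self.sparsity == "max"
        best = (np.inf, 1, 0.0)
        for thr in thr_grid:
            for c in range(1, max_c + 1):
                d = self._cv_score(Xs, times, events, folds, c, thr, max_sparse)
                if d < best[0] - 1e-9:
                    best = (d, c, thr)
        _, self.n_components_, self.threshold_ = best

        dr = deviance_residuals(times, events)
        self.W_, self.P_ = _spls_fit(Xs, dr, self.n_components_,
                                     self.threshold_, max_sparse)
        self.rotation_ = _rotation(self.W_, self.P_)
        scores = Xs @ self.rotation_
        y = Surv.from_arrays(events.astype(bool), times)
        self.cox_ = CoxPHSurvivalAnalysis(ties="breslow", alpha=1e-8)
        self.cox_.fit(scores, y)
        self._store_baseline(X, times, events)
        return self

    def linear_predictor(self, X):
        Xs = self._check_columns(X)
        Xz = (Xs.to_numpy(dtype=float) - self.center_) / self.scale_
        return (Xz @ self.rotation_) @ self.cox_.coef_
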