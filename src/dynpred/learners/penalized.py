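"""Penalized Cox learners: lasso, ridge and elastic net.

Predictors are z-scored internally. The lasso / elastic-net coefficient path
comes from the Coxnet solver; the ridge variant penalizes the Breslow partial
likelihood directly. The penalty weight is tuned by internal K-fold
cross-validation of the Verweij & Van Houwelingen partial-likelihood
deviance; the elastic net tunes the l1/l2 mixing over a fixed grid jointly
with the penalty.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .base import RegressionSurvivalLearner, breslow_loglik

__all__ = ["PenalizedCoxLearner"]

ELASTIC_MIXING_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
RIDGE_ALPHA_GRID = tuple(np.logspace(-3, 3, 25))


def _fold_ids(n, n_folds, rng):
    return np.asarray(rng.permutation(n) % n_folds)


class PenalizedCoxLearner(RegressionSurvivalLearner):
    """Penalized Cox model.

    ``penalty``: ``"lasso"`` (l1), ``"ridge"`` (l2) or ``"elastic"``
    (mixing tuned over {0.1, ..., 0.9}).
    """

    def __init__(self, penalty: str = "lasso", n_folds: int = 10, seed: int = 0):
        if penalty not in ("lasso", "ridge", "elastic"):
            raise ValueError(f"unknown penalty {penalty!r}")
        self.penalty = penalty
        self.n_folds = n_folds
        self.seed = seed
        self.name = f"pcox_{penalty}"

    # -- internals ------------------------------------------------------------

    def _standardize(self, X):
        Xv = X.to_numpy(dtype=float)
        return (Xv - self.center_) / self.scale_

    def _cv_coxnet(self, Xs, times, events, y, l1_ratio, folds):
        path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=50,
                                      alpha_min_ratio=0.01)
        path.fit(Xs, y)
        alphas = path.alphas_
        dev = np.zeros(len(alphas))
        for k in range(self.n_folds):
            tr = folds != k
            sub = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio,
                                         alphas=alphas, alpha_min_ratio=0.01)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub.fit(Xs[tr], y[tr])
            for j, a in enumerate(alphas):
                lp = Xs @ sub.coef_[:, min(j, sub.coef_.shape[1] - 1)]
                dev[j] += -2 * (breslow_loglik(lp, times, events)
                                - breslow_loglik(lp[tr], times[tr], events[tr]))
        best = int(np.argmin(dev))
        return path.coef_[:, best], float(alphas[best]), float(dev[best])

    def _cv_ridge(self, Xs, times, events, y, folds):
        best = (np.inf, None, None)
        for a in RIDGE_ALPHA_GRID:
            dev = 0.0
            for k in range(self.n_folds):
                tr = folds != k
                m = CoxPHSurvivalAnalysis(alpha=a, ties="breslow")
                m.fit(Xs[tr], y[tr])
                lp = Xs @ m.coef_
                dev += -2 * (breslow_loglik(lp, times, events)
                             - breslow_loglik(lp[tr], times[tr], events[tr]))
            if dev < best[0]:
                m_full = CoxPHSurvivalAnalysis(alpha=a, ties="breslow").fit(Xs, y)
                best = (dev, m_full.coef_, a)
        return best[1], best[2], best[0]

    def fit(self, X: pd.DataFrame, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        y = Surv.from_arrays(events.astype(bool), times)
        self.feature_names_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        self.center_ = Xv.mean(0)
        self.scale_ = Xv.std(0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (Xv - self.center_) / self.scale_
        rng = np.random.default_rng(self.seed)
        folds = _fold_ids(len(times), self.n_folds, rng)

        if self.penalty == "ridge":
            coef, alpha, dev = self._cv_ridge(Xs, times, events, y, folds)
            self.l1_ratio_ = 0.0
        elif self.penalty == "lasso":
            coef, alpha, dev = self._cv_coxnet(Xs, times, events, y, 1.0, folds)
            self.l1_ratio_ = 1.0
        else:
            best = (np.inf, None, None, None)
            for r in ELASTIC_MIXING_GRID:
                c, a, d = self._cv_coxnet(Xs, times, events, y, r, folds)
                if d < best[0]:
                    best = (d, c, a, r)
            dev, coef, alpha, self.l1_ratio_ = best
        self.coef_ = pd.Series(coef, index=self.feature_names_)
        self.alpha_ = alpha
        self.cv_deviance_ = dev
        if np.allclose(coef, 0.0):
            warnings.warn("all penalized coefficients are zero (null model)",
                          RuntimeWarning)
        self.selected_ = [c for c, v in self.coef_.items() if v != 0.0]
        self._store_baseline(X, times, events)
        return self

    def linear_predictor(self, X):
        Xs = self._check_columns(X)
        return self._standardize(Xs) @ self.coef_.to_numpy()
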