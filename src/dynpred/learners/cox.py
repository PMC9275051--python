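"""Cox proportional hazards learners: all covariates, or backward selection.

The full model is estimated by Breslow partial likelihood (scikit-survival).
The selecting variant performs backward elimination on AIC starting from the
full model, dropping at each step the covariate whose removal lowers AIC the
most, until no removal improves it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .base import RegressionSurvivalLearner, breslow_loglik

__all__ = ["CoxLearner"]


def drop_aliased(X: pd.DataFrame, tol: float = 1e-8) -> list:
    """Columns forming a full-rank design, in original order.

    Trajectory summaries are exactly collinear by construction (level, slope
    and cumulative level are affine in the predicted random effects), so the
    unpenalized Cox fit drops aliased columns first — the same behavior as
    aliasing in R's model fitters.
    """
    from scipy.linalg import qr

    Xv = X.to_numpy(dtype=float)
    Xv = Xv - Xv.mean(0)
    sd = Xv.std(0)
    keep_nonconst = sd > 0
    Xs = Xv[:, keep_nonconst] / sd[keep_nonconst]
    if Xs.shape[1] == 0:
        return []
    _, R, piv = qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0]))
    cols = np.asarray(X.columns)[keep_nonconst]
    kept = sorted(piv[:rank])
    return [str(c) for c in cols[kept]]


class CoxLearner(RegressionSurvivalLearner):
    """Unpenalized Cox model (``select=False``: *Cox-AllVar*) or AIC-based
    backward selection from the full model (``select=True``: *Cox-SelectVar*)."""

    def __init__(self, select: bool = False, alpha: float = 0.0):
        self.select = select
        self.alpha = alpha  # optional tiny ridge for ill-conditioned fits
        self.name = "cox_select" if select else "cox_all"

    def _fit_subset(self, X, y, cols):
        if not cols:
            return None
        import warnings as _w
        Xv = X[cols].to_numpy(dtype=float)
        # near-collinear summary designs can defeat the Newton solver; retry
        # with a vanishing ridge before giving up (estimates unchanged to
        # numerical precision on well-posed problems)
        for alpha in (self.alpha, 1e-4, 1e-2, 1.0):
            try:
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    model = CoxPHSurvivalAnalysis(alpha=alpha, ties="breslow")
                    model.fit(Xv, y)
                if np.all(np.isfinite(model.coef_)):
                    if alpha != self.alpha:
                        _w.warn(f"Cox fit stabilized with ridge alpha={alpha}",
                                RuntimeWarning)
                    return model
            except (np.linalg.LinAlgError, ValueError):
                continue
        raise RuntimeError(
            f"Cox partial-likelihood fit failed to converge on {len(cols)} "
            "predictors")

    def fit(self, X: pd.DataFrame, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        y = Surv.from_arrays(events.astype(bool), times)
        cols = drop_aliased(X)
        if events.sum() < len(cols):
            import warnings
            warnings.warn(
                f"{events.sum()} events for {len(cols)} predictors; "
                "Cox estimates may be unstable", RuntimeWarning)
        model = self._fit_subset(X, y, cols)

        if self.select and cols:
            def aic(m, cs):
                lp = (m.predict(X[cs].to_numpy(dtype=float)) if cs
                      else np.zeros(len(X)))
                return -2 * breslow_loglik(lp, times, events) + 2 * len(cs)

            current, cur_aic = cols, aic(model, cols)
            improved = True
            while improved and current:
                improved = False
                best = (cur_aic, None, None)
                for c in current:
                    reduced = [x for x in current if x != c]
                    m = self._fit_subset(X, y, reduced)
                    a = aic(m, reduced)
                    if a < best[0] - 1e-9:
                        best = (a, reduced, m)
                if best[1] is not None:
                    cur_aic, current, model = best[0], best[1], best[2]
                    improved = True
            cols = current

        self.feature_names_ = cols
        self.model_ = model
        self.coef_ = pd.Series(
            model.coef_ if model is not None else [], index=cols)
        self._all_columns = list(X.columns)
        self._store_baseline(X, times, events)
        return self

    def linear_predictor(self, X):
        if not self.feature_names_:
            return np.zeros(len(X))
        Xs = self._check_columns(X)
        return self.model_.predict(Xs.to_numpy(dtype=float))
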