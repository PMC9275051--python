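"""Landmark-conditional predictive-accuracy estimators.

All estimators work on the landmark time scale (time 0 = landmark, every
subject at risk). Right censoring before the horizon makes the window
status ``D`` unknown for some subjects; the Brier score and the
time-dependent AUC handle this by inverse-probability-of-censoring
weighting (IPCW): observed events before the horizon are weighted by
``1 / G(T^-)`` and horizon survivors by ``1 / G(t_Hor)``, where ``G`` is
the Kaplan-Meier estimator of the censoring distribution; subjects censored
before the horizon get weight zero. With no censoring both estimators
reduce exactly to their complete-data versions. MSEP compares predicted
probabilities with the generator's true probabilities and therefore exists
only in simulation.
"""

from __future__ import annotations

import numpy as np

from .learners.base import StepFunction

__all__ = ["censoring_survival", "ipcw_weights", "brier_ipcw", "auc_ipcw", "msep"]


def censoring_survival(times, events) -> StepFunction:
    """Kaplan-Meier estimator of the censoring survival function G.

    The roles of event and censoring are swapped: censorings are the
    "events". G steps down at censoring times; ties between an event and a
    censoring at the same time follow the convention that events precede
    censorings (the censored subject is removed from the risk set after the
    event is counted).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cens = 1 - events
    if cens.sum() == 0:
        return StepFunction([], [], initial=1.0)
    ctimes = np.unique(times[cens == 1])
    surv = []
    g = 1.0
    for t in ctimes:
        # events at t leave the risk set before censorings at t
        at_risk = (times > t).sum() + ((times == t) & (cens == 1)).sum()
        d = ((times == t) & (cens == 1)).sum()
        g *= 1.0 - d / at_risk
        surv.append(g)
    return StepFunction(ctimes, np.asarray(surv), initial=1.0)


def ipcw_weights(times, events, t_hor, G: StepFunction | None = None):
    """IPCW weight per subject: ``1{T<=t_hor, delta=1}/G(T^-)`` for observed
    events, ``1{T>t_hor}/G(t_hor)`` for horizon survivors, 0 otherwise."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if G is None:
        G = censoring_survival(times, events)
    w = np.zeros(len(times))
    is_case = (times <= t_hor) & (events == 1)
    is_ctrl = times > t_hor
    if is_case.any():
        g_left = np.atleast_1d(G.at(times[is_case], side="left"))
        if np.any(g_left <= 0):
            raise ValueError("censoring survival is zero at an event time; "
                             "IPCW weights undefined")
        w[is_case] = 1.0 / g_left
    if is_ctrl.any():
        g_hor = float(np.atleast_1d(G.at(t_hor))[0])
        if g_hor <= 0:
            raise ValueError("censoring survival is zero at the horizon; "
                             "IPCW weights undefined")
        w[is_ctrl] = 1.0 / g_hor
    return w, is_case, is_ctrl


def brier_ipcw(predictions, times, events, t_hor) -> float:
    """IPCW Brier score of predicted event probabilities over the window.

    ``sum_i w_i (D_i - pi_i)^2 / sum_i w_i`` with D the window event status.
    """
    predictions = np.asarray(predictions, dtype=float)
    w, is_case, is_ctrl = ipcw_weights(times, events, t_hor)
    D = np.where(is_case, 1.0, 0.0)
    num = np.sum(w * (D - predictions) ** 2)
    den = np.sum(w)
    if den == 0:
        raise ValueError("no subject has positive IPCW weight")
    return float(num / den)


def auc_ipcw(predictions, times, events, t_hor) -> float:
    """IPCW time-dependent AUC: weighted probability that a case (event in
    the window) is ranked above a control (event-free at the horizon), ties
    counting one half."""
    predictions = np.asarray(predictions, dtype=float)
    w, is_case, is_ctrl = ipcw_weights(times, events, t_hor)
    if not is_case.any() or not is_ctrl.any():
        raise ValueError("need at least one case and one control for AUC")
    pc, wc = predictions[is_case], w[is_case]
    pk, wk = predictions[is_ctrl], w[is_ctrl]
    gt = (pc[:, None] > pk[None, :]).astype(float)
    eq = (pc[:, None] == pk[None, :]).astype(float)
    pair_w = wc[:, None] * wk[None, :]
    return float(np.sum(pair_w * (gt + 0.5 * eq)) / np.sum(pair_w))


def msep(predictions, true_probabilities) -> float:
    """Mean squared error of prediction against the true (generator-known)
    event probabilities: ``mean((pi_hat - pi0)^2)``."""
    predictions = np.asarray(predictions, dtype=float)
    true_probabilities = np.asarray(true_probabilities, dtype=float)
    if predictions.shape != true_probabilities.shape:
        raise ValueError("prediction and truth vectors must have equal length")
    return float(np.mean((predictions - true_probabilities) ** 2))
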