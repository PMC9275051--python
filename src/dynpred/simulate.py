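"""Synthetic cohorts for the landmark dynamic-prediction study conditions.

The generator defines the package's simulation study conditions: subjects
at risk at a 4-year landmark carry repeated measures of 17 biomarkers,
observed at 5 visits jittered around -4, -3, -2, -1 and 0 years before the
landmark (gaussian jitter with variance 0.15). Each marker follows an
individual polynomial linear mixed model: 9 markers are quadratic in time
(3 correlated-free random effects), 6 linear (2) and 2 intercept-only (1),
giving 41 random effects and 41 + 3*17 = 92 trajectory summaries per
subject. Ten baseline covariates are added: 5 standard normal, 5 Bernoulli
with success probability one half.

The event risk after the landmark follows a proportional-hazards model with
Weibull baseline (cumulative hazard ``lambda * t^shape``). The linear
predictor is built from an "active" subset of the true summaries — the
level and slope of 9 markers (18 summaries) or of 2 markers (4 summaries) —
entered linearly, linearly with cross-marker interactions, or non-linearly
(squared terms and median binarization). The Weibull rate is calibrated
once per scenario so about 40% of at-risk subjects experience the event
within the 3-year horizon, and censoring is uniform over
``(t_LM, t_LM + 2 t_Hor)``. Event times are drawn conditionally on surviving
to the landmark, so every generated subject is at risk by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .basis import PolynomialBasis
from .data import LandmarkConfig, LongitudinalDataset, SurvivalTable
from .summaries import summary_names

logger = logging.getLogger("dynpred")

__all__ = [
    "MarkerDesign", "ScenarioConfig", "SimulatedCohort",
    "default_marker_designs", "generate_visits", "generate_markers",
    "generate_covariates", "linear_predictor", "generate_event_times",
    "generate_cohort", "marker_specs_for", "run_scenario",
]

T_LANDMARK = 4.0
T_HORIZON = 3.0
VISIT_OFFSETS = (-4.0, -3.0, -2.0, -1.0, 0.0)
VISIT_JITTER_VAR = 0.15
TARGET_EVENT_RATE = 0.40


@dataclass(frozen=True)
class MarkerDesign:
    """Generating linear mixed model of one marker, in time centered at the
    landmark (s = t - t_LM in [-4, 0])."""

    name: str
    beta: tuple                 # fixed polynomial coefficients, low order first
    re_sd: tuple                # random-effect SDs (intercept, slope, curvature)
    sigma: float                # residual SD

    @property
    def q(self) -> int:
        return len(self.re_sd)

    @property
    def degree(self) -> int:
        return len(self.beta) - 1

    def basis(self, t_landmark=T_LANDMARK) -> PolynomialBasis:
        return PolynomialBasis(self.degree, center=t_landmark)

    def random_basis(self, t_landmark=T_LANDMARK) -> PolynomialBasis:
        return PolynomialBasis(self.q - 1, center=t_landmark)


def default_marker_designs() -> list:
    """The 17 default marker designs: 9 quadratic, 6 linear, 2 intercept-only.

    Residual SD 0.55 against a unit random-intercept SD gives
    signal-to-noise about 2 at the landmark. Fixed-effect shapes vary across
    markers (rising, falling, curved) so no two markers are exchangeable.
    """
    designs = []
    quad_beta = [
        (2.0, 0.30, 0.05), (3.0, -0.25, 0.04), (1.5, 0.20, -0.05),
        (4.0, -0.35, -0.03), (2.5, 0.15, 0.06), (3.5, 0.40, -0.04),
        (1.0, -0.20, 0.03), (2.8, 0.25, -0.06), (3.2, -0.30, 0.05),
    ]
    for i, b in enumerate(quad_beta):
        designs.append(MarkerDesign(f"m{i + 1:02d}", b, (1.0, 0.30, 0.10), 0.55))
    lin_beta = [(2.2, 0.35), (3.1, -0.30), (1.8, 0.25),
                (2.6, -0.20), (3.4, 0.30), (1.4, -0.35)]
    for i, b in enumerate(lin_beta):
        designs.append(MarkerDesign(f"m{i + 10:02d}", b, (1.0, 0.30), 0.55))
    for i, b0 in enumerate((2.0, 3.0)):
        designs.append(MarkerDesign(f"m{i + 16:02d}", (b0,), (1.0,), 0.55))
    assert sum(d.q + 3 for d in designs) == 92
    return designs


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``n_active`` in {18, 4}: number of true summaries driving the hazard
    (level and slope of 9 or of 2 markers). ``link`` in {"linear",
    "interactions", "nonlinear"}. The Weibull rate and the linear-predictor
    offset are calibrated deterministically at construction time from
    ``calibration_seed`` to hit ``target_rate`` events within the horizon.
    """

    n_active: int = 18
    link: str = "linear"
    n_subjects: int = 500
    weibull_shape: float = 1.5
    t_landmark: float = T_LANDMARK
    t_horizon: float = T_HORIZON
    coef: float = 0.35
    covariate_coef: float = 0.20
    target_rate: float = TARGET_EVENT_RATE
    calibration_seed: int = 123456
    designs: tuple = field(default_factory=lambda: tuple(default_marker_designs()))

    def __post_init__(self):
        if self.n_active not in (18, 4):
            raise ValueError("n_active must be 18 or 4")
        if self.link not in ("linear", "interactions", "nonlinear"):
            raise ValueError(f"unknown link form {self.link!r}")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.weibull_shape <= 0:
            raise ValueError("weibull shape must be > 0")

    @property
    def active_markers(self) -> list:
        return [d.name for d in self.designs[: self.n_active // 2]]

    @property
    def active_summaries(self) -> list:
        out = []
        for m in self.active_markers:
            out += [f"{m}.level", f"{m}.slope"]
        return out

    @property
    def landmark_config(self) -> LandmarkConfig:
        return LandmarkConfig(self.t_landmark, self.t_horizon,
                              cumulative_window=4.0)


def generate_visits(n_subjects, rng, t_landmark=T_LANDMARK,
                    jitter_var=VISIT_JITTER_VAR) -> np.ndarray:
    """Visit times, shape (n_subjects, 5): jittered theoretical offsets
    (gaussian, variance ``jitter_var``) around the landmark, clipped to
    ``<= t_landmark``."""
    offsets = np.asarray(VISIT_OFFSETS)
    jitter = np.zeros((n_subjects, offsets.size))
    if jitter_var > 0:
        jitter = rng.normal(0.0, np.sqrt(jitter_var), jitter.shape)
    v = np.minimum(t_landmark + offsets + jitter, t_landmark)
    # clipping can tie several visits at the landmark; spread exact ties by
    # an epsilon so (subject, marker, time) stays unique
    capped = np.isclose(v, t_landmark)
    for i in np.where(capped.sum(1) > 1)[0]:
        k = int(capped[i].sum())
        v[i, capped[i]] = t_landmark - 1e-6 * np.arange(k - 1, -1, -1)
    return v


def generate_markers(n_subjects, rng, designs=None, t_landmark=T_LANDMARK,
                     jitter_var=VISIT_JITTER_VAR):
    """Longitudinal marker data plus true random effects.

    Returns ``(LongitudinalDataset, dict marker -> (n_subjects, q) true b)``.
    """
    designs = list(designs or default_marker_designs())
    frames = []
    true_b = {}
    ids = np.arange(1, n_subjects + 1)
    for d in designs:
        if np.any(np.asarray(d.re_sd) < 0):
            raise ValueError(f"negative random-effect SD in design {d.name}")
        visits = generate_visits(n_subjects, rng, t_landmark, jitter_var)
        b = rng.normal(0.0, 1.0, (n_subjects, d.q)) * np.asarray(d.re_sd)
        true_b[d.name] = b
        flat_t = visits.ravel()
        X = d.basis(t_landmark).design(flat_t)
        Z = d.random_basis(t_landmark).design(flat_t)
        sid = np.repeat(ids, visits.shape[1])
        y = X @ np.asarray(d.beta) + np.einsum("nj,nj->n", Z, b[sid - 1]) \
            + rng.normal(0.0, d.sigma, flat_t.size)
        frames.append(pd.DataFrame(
            {"id": sid, "time": flat_t, "marker": d.name, "value": y}))
    long = LongitudinalDataset(pd.concat(frames, ignore_index=True))
    return long, true_b


def true_summaries(designs, true_b, t_landmark=T_LANDMARK,
                   window=4.0) -> pd.DataFrame:
    """True 92-column summary matrix from the generating models."""
    cols = {}
    n = next(iter(true_b.values())).shape[0]
    for d in designs:
        b = true_b[d.name]
        fb, rb = d.basis(t_landmark), d.random_basis(t_landmark)
        beta = np.asarray(d.beta)
        level = fb.design([t_landmark])[0] @ beta + b @ rb.design([t_landmark])[0]
        slope = fb.deriv([t_landmark])[0] @ beta + b @ rb.deriv([t_landmark])[0]
        cumul = fb.integral(t_landmark - window, t_landmark) @ beta \
            + b @ rb.integral(t_landmark - window, t_landmark)
        block = np.column_stack([b, level, slope, cumul])
        for j, name in enumerate(summary_names(d.name, d.q)):
            cols[name] = block[:, j]
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="id"))


def generate_covariates(n_subjects, rng) -> pd.DataFrame:
    """10 baseline covariates: 5 standard normal, 5 Bernoulli(0.5)."""
    cols = {f"xnorm{j + 1}": rng.normal(0.0, 1.0, n_subjects) for j in range(5)}
    cols.update({f"xbin{j + 1}": rng.binomial(1, 0.5, n_subjects).astype(float)
                 for j in range(5)})
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n_subjects + 1, name="id"))


# population mean and SD of each active summary under the default designs
# (landmark-centered bases: level has mean beta0 and SD re_sd[0], slope mean
# beta1 and SD re_sd[1]); active summaries enter the hazard standardized so
# coefficients are comparable and squared/interaction terms are genuinely
# non-linear rather than dominated by their linear part
def _summary_moments(scenario: ScenarioConfig):
    means, scales = [], []
    by_name = {d.name: d for d in scenario.designs}
    for s in scenario.active_summaries:
        marker, kind = s.split(".")
        d = by_name[marker]
        if kind == "level":
            means.append(d.beta[0])
            scales.append(max(d.re_sd[0], 1e-6))
        else:
            means.append(d.beta[1])
            scales.append(max(d.re_sd[1], 1e-6))
    return np.asarray(means), np.asarray(scales)


def linear_predictor(gamma0: pd.DataFrame, X: pd.DataFrame,
                     scenario: ScenarioConfig) -> np.ndarray:
    """Scenario linear predictor on the hazard scale (before calibration
    offset). Active summaries are standardized by their population scale so
    coefficients are comparable across level and slope terms."""
    act = scenario.active_summaries
    means, scales = _summary_moments(scenario)
    Z = (gamma0[act].to_numpy() - means) / scales
    c = scenario.coef
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(Z.shape[1])])
    xc = np.zeros(len(X))
    for j, col in enumerate(["xnorm1", "xnorm2", "xbin1", "xbin2"]):
        xc += scenario.covariate_coef * (1 if j % 2 == 0 else -1) * X[col].to_numpy()

    if scenario.link == "linear":
        eta = Z @ (c * signs) + xc
    elif scenario.link == "interactions":
        eta = Z @ (c * signs) + xc
        levels = Z[:, 0::2]  # level columns of the active markers
        for j in range(levels.shape[1] - 1):
            eta += 0.5 * c * (1 if j % 2 == 0 else -1) \
                * levels[:, j] * levels[:, j + 1]
    else:  # nonlinear: squared terms and median binarization, no linear part
        med = np.median(Z, axis=0)
        eta = xc.copy()
        for j in range(Z.shape[1]):
            s = 1.0 if j % 2 == 0 else -1.0
            eta += s * c * (Z[:, j] ** 2) + 1.5 * s * c * (Z[:, j] > med[j])
    return eta


def _calibrate(scenario: ScenarioConfig):
    """Deterministic calibration of the linear-predictor offset and the
    Weibull rate so the mean true probability within the horizon is
    ``target_rate``; cached on the config object."""
    cache = getattr(scenario, "_calibration", None)
    if cache is not None:
        return cache
    rng = np.random.default_rng(scenario.calibration_seed)
    n = 4000
    _, true_b = _draw_true_effects(n, rng, scenario)
    gamma0 = true_summaries(scenario.designs, true_b, scenario.t_landmark)
    X = generate_covariates(n, rng)
    eta = linear_predictor(gamma0, X, scenario)
    offset = float(eta.mean())
    eta = eta - offset
    k = scenario.weibull_shape
    t0, t1 = scenario.t_landmark, scenario.t_landmark + scenario.t_horizon
    dt = t1 ** k - t0 ** k

    def mean_rate(log_lam):
        return np.mean(1.0 - np.exp(-np.exp(log_lam) * np.exp(eta) * dt)) \
            - scenario.target_rate

    log_lam = brentq(mean_rate, -20.0, 5.0)
    cal = {"offset": offset, "rate": float(np.exp(log_lam))}
    object.__setattr__(scenario, "_calibration", cal)
    return cal


def _draw_true_effects(n, rng, scenario):
    """Random effects for all markers without simulating measurements (used
    for calibration); mirrors generate_markers' effect distributions."""
    true_b = {}
    for d in scenario.designs:
        true_b[d.name] = rng.normal(0.0, 1.0, (n, d.q)) * np.asarray(d.re_sd)
    return None, true_b


def generate_event_times(eta, scenario: ScenarioConfig, rng):
    """Observed times and indicators, conditional on being at risk at the
    landmark.

    True times are drawn by inverse transform from the conditional Weibull
    survival ``S(t | T > t_LM) = exp(-lambda e^eta (t^k - t_LM^k))``;
    censoring is uniform on ``(t_LM, t_LM + 2 t_Hor)``. Returns
    ``(T_star, delta, pi0)`` with ``pi0`` the true probability of the event
    within the horizon.
    """
    cal = _calibrate(scenario)
    lam, k = cal["rate"], scenario.weibull_shape
    t0 = scenario.t_landmark
    risk = lam * np.exp(eta)
    u = rng.uniform(size=len(eta))
    T = (t0 ** k - np.log(u) / risk) ** (1.0 / k)
    C = t0 + rng.uniform(0.0, 2.0 * scenario.t_horizon, len(eta))
    T_star = np.minimum(T, C)
    delta = (T <= C).astype(int)
    t1 = t0 + scenario.t_horizon
    pi0 = 1.0 - np.exp(-risk * (t1 ** k - t0 ** k))
    return T_star, delta, pi0


@dataclass
class SimulatedCohort:
    long: LongitudinalDataset
    surv: SurvivalTable
    gamma0: pd.DataFrame          # true 92-column summary matrix
    pi0: np.ndarray               # true P(event within horizon | at risk)
    eta: np.ndarray
    scenario: ScenarioConfig


def generate_cohort(scenario: ScenarioConfig, seed: int) -> SimulatedCohort:
    """One cohort of at-risk subjects under the scenario's study conditions."""
    rng = np.random.default_rng(seed)
    n = scenario.n_subjects
    long, true_b = generate_markers(n, rng, scenario.designs,
                                    scenario.t_landmark)
    gamma0 = true_summaries(scenario.designs, true_b, scenario.t_landmark)
    X = generate_covariates(n, rng)
    eta = linear_predictor(gamma0, X, scenario) - _calibrate(scenario)["offset"]
    T_star, delta, pi0 = generate_event_times(eta, scenario, rng)
    surv = SurvivalTable(pd.DataFrame(
        {"id": np.arange(1, n + 1), "time": T_star, "event": delta}
    ).join(X.reset_index(drop=True)))
    return SimulatedCohort(long, surv, gamma0, pi0, eta, scenario)


def marker_specs_for(scenario: ScenarioConfig) -> dict:
    """fit_marker_model keyword arguments matching the generating designs."""
    return {
        d.name: {
            "family": "gaussian",
            "fixed_basis": d.basis(scenario.t_landmark),
            "random_basis": d.random_basis(scenario.t_landmark),
        }
        for d in scenario.designs
    }


def run_scenario(scenario: ScenarioConfig, learner_specs, n_replicates: int,
                 seed: int = 0, validation_seed: int | None = None,
                 progress: bool = False) -> pd.DataFrame:
    """Train on ``n_replicates`` learning cohorts, assess every method on one
    fixed external validation cohort; returns a tidy table with one row per
    (replicate, method) carrying BS, AUC and MSEP."""
    from .metrics import auc_ipcw, brier_ipcw, msep
    from .summaries import build_summary_matrix
    from .learners import make_learner

    cfg = scenario.landmark_config
    specs = marker_specs_for(scenario)
    vseed = validation_seed if validation_seed is not None else seed + 10 ** 6
    valid = generate_cohort(scenario, vseed)
    v_times = valid.surv.frame["time"].to_numpy() - cfg.t_landmark
    v_events_win = ((valid.surv.frame["event"] == 1)
                    & (valid.surv.frame["time"] < cfg.t_end)).to_numpy().astype(int)

    from .superlearner import fit_all_markers
    rows = []
    for r in range(n_replicates):
        cohort = generate_cohort(scenario, seed + r)
        models = fit_all_markers(cohort.long, specs)
        ld_train = build_summary_matrix(models, cohort.long, cohort.surv, cfg)
        ld_valid = build_summary_matrix(models, valid.long, valid.surv, cfg)
        for spec in learner_specs:
            try:
                learner = make_learner(spec).fit_landmark(ld_train)
                pred = learner.predict_probability(ld_valid.features,
                                                   cfg.t_horizon)
                rows.append({
                    "replicate": r, "method": spec.method,
                    "BS": brier_ipcw(pred, v_times, v_events_win, cfg.t_horizon),
                    "AUC": auc_ipcw(pred, v_times, v_events_win, cfg.t_horizon),
                    "MSEP": msep(pred, valid.pi0),
                    "error": "",
                })
            except Exception as err:  # record failure, continue replicate
                logger.warning("replicate %d method %s failed: %s",
                               r, spec.method, err)
                rows.append({"replicate": r, "method": spec.method,
                             "BS": np.nan, "AUC": np.nan, "MSEP": np.nan,
                             "error": str(err)})
        if progress:
            print(f"replicate {r + 1}/{n_replicates} done")
    return pd.DataFrame(rows)
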