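# Methods

## The prediction problem

For a subject still event-free at a landmark time `t_LM`, we want the
probability of the event within a horizon window,

    pi(t_LM, t_Hor) = P(T <= t_LM + t_Hor | T > t_LM, marker history up to t_LM, X),

using the histories of K intermittently measured, error-prone markers plus P
baseline covariates. Joint models become intractable beyond a few markers;
the landmark strategy instead conditions on the at-risk sample and compresses
each marker history into a fixed-length feature vector before handing the
problem to survival prediction methods that tolerate many correlated
predictors.

The estimation pipeline has four steps:

1. **Marker models.** Each marker is modeled independently by a generalized
   mixed model `g(E[Y_ij | b_i]) = X(t_ij)'beta + Z(t_ij)'b_i` with
   `b_i ~ N(0, B)` — identity link with gaussian residuals for continuous
   markers, logit link for binary ones — fitted on the at-risk subjects'
   measurements with `t_ij <= t_LM`. Time bases are polynomials or natural
   cubic splines; both expose analytic derivatives and exact integrals.
2. **Trajectory summaries.** Per subject and marker: the predicted random
   effects (BLUP `b_hat = B Z' V^{-1}(y - X beta)` for gaussian markers,
   posterior mode for binary ones; empty histories fall back to the prior
   mean 0), the error-free level and slope at `t_LM`, and the cumulative
   level over a trailing window `[t_LM - W, t_LM]`. Binary-marker summaries
   stay on the logit scale so they feed linear predictors sensibly. The
   concatenation `Gamma_i` plus covariates `X_i` is the feature matrix.
3. **Survival learners.** Eleven sub-methods in four families, all behind a
   single fit/predict contract: Cox with all variables or AIC backward
   selection; penalized Cox with lasso, ridge or elastic-net penalty
   (penalty tuned by internal 10-fold cross-validation of the Verweij-Van
   Houwelingen partial-likelihood deviance; elastic mixing tuned over
   {0.1, ..., 0.9}); sparse PLS on null-model deviance residuals with no /
   maximal / tuned per-component soft-thresholding and a Cox model on the
   scores; random survival forests with log-rank splitting (defaults
   `M = floor(sqrt(P))` candidate predictors per node, minimal node size
   `S = 15`, `B = 500` trees; optionally `(M, S)` tuned on the out-of-bag
   error `1 - Harrell C`, and VIMP-positive variable selection).
4. **Probabilities.** Regression families:
   `pi = 1 - exp(-Lambda0(t_Hor) exp(lp))` with a Breslow baseline
   cumulative hazard on the landmark time scale; forests:
   `pi = 1 - exp(-mean_b Lambda_b(t_Hor))` over the trees' leaf
   Nelson-Aalen curves. A superlearner blends the methods with convex
   weights minimizing the cross-validated IPCW Brier score.

## Accuracy estimators

All metrics condition on the at-risk sample with time origin at the
landmark. The window status `D` is unknown for subjects censored before the
horizon, so the Brier score and time-dependent cumulative/dynamic AUC are
inverse-probability-of-censoring weighted: events before the horizon weigh
`1/G(T^-)`, horizon survivors `1/G(t_Hor)`, censored-in-window subjects 0,
with `G` the Kaplan-Meier estimator of the censoring distribution computed
marginally on the same sample (ties between events and censorings resolved
events-first). Both estimators reduce exactly to their complete-data forms
under no censoring; the Brier score is normalized by the weight sum. MSEP —
the mean squared difference between predicted and generating probabilities —
exists only in simulation.

## Cross-validation layers

Assessment uses K-fold cross-validation with the *entire* pipeline refitted
inside each training fold: held-out subjects' summaries are always computed
through marker models that never saw their data or outcomes (the test suite
contains a leakage contrast check). The superlearner adds an inner
cross-validation within each training sample to produce the out-of-fold
member predictions its weights are trained on, and each learner may run its
own innermost tuning loop (CV or bootstrap/OOB). Folds are drawn so every
fold contains at least one event (refolded otherwise, logged), and a
per-fold two-sample log-rank p-value against the complement is logged as a
balance diagnostic. Weight optimization uses a softmax reparametrization
with multiple deterministic starts (Nelder-Mead), a `1e-8` ridge on
`||w||^2` breaking flat objectives toward the most uniform minimizer; the
test suite validates it against a dense simplex grid for up to three
members.

## Mixed-model estimation

The gaussian fitter maximizes the exact marginal likelihood with the fixed
effects profiled out, optimizing over the Cholesky factor of `B` (log
diagonal) and `log sigma` with L-BFGS-B; subjects are grouped by visit count
so the per-subject linear algebra is batched. It matches statsmodels MixedLM
(ML) to optimizer precision while being an order of magnitude faster on many
small fits — this matters because nested cross-validation and the simulation
study refit every marker model dozens of times. `sigma` is bounded below at
`1e-6 * sd(y)` so zero-noise degenerate data land on the boundary instead of
diverging; a near-singular `B` triggers a warning and a refit with a bounded
Cholesky diagonal. Binary markers use a logistic random-intercept model
(richer random structures are not supported for binary markers) fitted by
adaptive Gauss-Hermite quadrature: 15 nodes centered per subject at the
posterior mode with curvature scaling, mode found by damped Newton.
Individual predictions use the closed-form BLUP (gaussian) or the posterior
mode (binary), which the tests verify against numeric posterior
optimization.

Skewed continuous markers can be pre-transformed with a rank-based
inverse-normal (Blom) transform, applied once to a marker's pooled
measurements before any fitting. This is a deliberate, simpler stand-in for
spline-based normalization; it preserves ranks but compresses extreme
values, which is the main suspect for the Brier-score level difference noted
under "PBC application" below.

## Synthetic cohorts

The generator defines the package's study conditions. Subjects at risk at
`t_LM = 4` years carry 17 continuous markers observed at 5 visits jittered
N(0, 0.15) (variance; SD 0.387 years) around -4...0 years before the
landmark, clipped at the landmark (exact ties spread by 1e-6 years to keep
measurement keys unique). Marker trajectories are individual polynomials in
landmark-centered time: 9 quadratic (q = 3 random effects), 6 linear
(q = 2), 2 intercept-only (q = 1), so the summary vector has
`sum(q_k + 3) = 92` entries. Random-effect SDs are (1.0, 0.30, 0.10) down
the polynomial orders with residual SD 0.55 — signal-to-noise about 2 at the
landmark; fixed-effect shapes vary across markers. Ten covariates: 5
standard normal, 5 Bernoulli(0.5).

Event risk follows a proportional-hazards model with Weibull baseline
(`Lambda0(t) = lambda t^1.5`). The active predictors are the level and slope
of 9 markers (18 summaries) or of 2 markers (4 summaries), standardized by
their population moments, entering (i) linearly with alternating-sign
coefficients 0.35, (ii) plus cross-marker level interactions, or (iii)
non-linearly only — squares and above-median indicators — plus four
covariates at 0.2. The Weibull rate and a linear-predictor offset are
calibrated once per scenario (deterministic internal draw of 4000 subjects)
so the mean true event probability within the 3-year horizon is 40%. Event
times are drawn by inverse transform from the Weibull survival conditional
on `T > t_LM`, making every subject at risk by construction; censoring is
uniform on `(t_LM, t_LM + 2 t_Hor)`, yielding roughly 30% censoring in the
window. The generator returns the true summaries and true probabilities, so
MSEP and oracle checks are exact.

What the generator does not emulate: informative visit schedules, missing
visits, non-gaussian measurement error, binary markers (the simulated
cohorts are all-continuous; binary marker code is exercised by the PBC
application and unit tests), and association between censoring and
covariates. Passing simulation checks therefore demonstrates correctness of
the machinery under the stated design, not robustness to those features.

## Problem sizes used by the shipped runs

The scaled simulation comparison (tests and acceptance script) uses 18
active summaries, 20 learning replicates of N = 500 against one fixed
validation cohort, with Cox, lasso Cox and a 100-tree forest — sizes chosen
to make the ordering of median MSEP/Brier stable while keeping a full run in
minutes on one CPU; the forest ordering is insensitive to tree count beyond
about 100 trees here. Parameter-recovery checks use 100 replications of a
300-subject random-intercept model. The PBC analysis runs 10-fold
cross-validation with 1-2 repetitions.

## PBC application

The application rebuilds the pbc2-style table at run time from R's
`survival::pbcseq` (312 protocol patients; days converted to years; death as
the event, transplantation censored): 7 continuous markers
(inverse-normal-transformed; natural-spline fixed effects with one interior
knot at the median visit time, random intercept + slope) and 4 binary
markers (linear logit trend, random intercept), plus age, sex and treatment
arm. At the 4-year landmark 225 patients remain at risk, 34 of whom die
within the 3-year horizon. Cross-validated lasso discrimination comes out at
AUC ~ 0.86-0.87 with the familiar method ordering (lasso best, plain Cox
worst); the Brier level stabilizes around 0.10 across every marker
specification we tried — published analyses of these data with spline-based
marker normalization report somewhat lower values, so the normalization
choice likely matters more for calibration than for discrimination. The
baseline-information-only comparison
(first measured value per marker + covariates) degrades both Brier score and
AUC, quantifying the value of updating marker histories.

## Numerical and design choices

- Ties in partial likelihoods: Breslow everywhere, for cross-family
  consistency (including the hand-rolled partial log-likelihood used for AIC
  and cross-validated deviance).
- The unpenalized Cox learner drops aliased columns first (pivoted-QR rank
  detection) because level/slope/cumulative summaries are exactly affine in
  the predicted random effects; remaining near-collinearity is handled by
  retrying with a vanishing ridge (1e-4 -> 1e-2 -> 1), warned about, before
  declaring non-convergence.
- Predictors are z-scored inside penalized Cox and sPLS-DR only; Cox and
  forests see the raw scale.
- sPLS-DR components: PLS1 with per-component soft-thresholding at a
  fraction of the largest absolute loading weight (grid {0, .25, .5, .75,
  .9} for the tuned variant; "max" keeps exactly one loading); scores map
  through `W (P'W)^{-1}`; zero-variance predictors are dropped with a
  warning.
- Out-of-bag bookkeeping reuses the forest's bootstrap draw (per-tree
  unsampled indices); VIMP permutes a predictor within each tree's OOB
  sample and averages the concordance-error increase over trees; predictors
  a tree never split on contribute zero for that tree.
- The cumulative-level window defaults to the span from the earliest
  retained measurement to the landmark (full history) and is configurable.
- Natural cubic splines use the truncated-power natural parametrization
  (linear beyond boundary knots), boundary knots at the observed extremes
  and interior knots at quantiles of the distinct measurement times.
- Superlearner members are refit on the full training sample after weight
  estimation (standard stacking).

## Known limitations

- Binary markers support only a random intercept; continuous markers assume
  gaussian residuals after the optional rank transform.
- A single event type; no competing risks, no left truncation beyond the
  landmark itself, and one common landmark per fitted tool.
- The censoring model for IPCW is marginal; covariate-dependent censoring
  would bias the accuracy estimates.
- Backward selection refits one Cox model per candidate removal and is
  impractical beyond ~60 predictors; it is not part of the large-P
  simulation runs.
- AUC/Brier confidence intervals and calibration curves are out of scope.
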