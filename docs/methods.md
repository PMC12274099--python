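# Methods

## Setting and notation

A training sample consists of right-censored observations
`(T_i, δ_i, x_i), i = 1..n`, with `T_i = min(T̃_i, C_i)` the observed
follow-up time, `δ_i` the event indicator and `x_i` a covariate vector; the
latent event time `T̃_i` is assumed conditionally independent of the
censoring time `C_i` given `x_i`.  Fitted semiparametric models return a
predicted cumulative hazard `Ĥ(t|x)` that is a right-continuous step
function with jumps only at training event times; `Ŝ(t|x) = e^{−Ĥ(t|x)}`.
All step functions in the package evaluate right-continuously (a jump counts
at its own time) and left limits are available for the quantities that need
them (IPCW weights, window masses).

Ties in observed times are allowed in storage and are a detectable,
reportable condition (`SurvivalData.has_tied_event_times`).  Fitters resolve
event-time ties by the Breslow convention (full risk set in every tied
event's denominator) and treat events as preceding censorings at the same
time; the theory is cleanest with no ties, which holds almost surely for the
continuous generators used throughout.

## The smoothed predictive log-likelihood

The predictive log-likelihood of a test subject,
`L = δ log ĥ(t|x) − Ĥ(t|x)`, is degenerate for step-function predictions
because `ĥ = 0` off the training event times.  The package replaces `ĥ` by
a kernel estimate: with a uniform kernel and a data-adaptive window, the
smoothed hazard at a query time `t` is the mass of `dĤ(·|x)` inside the
window divided by the window length.

**Window rule.**  Let `L` be the `m` largest training event times strictly
below `t` and `U` the `m` smallest at or above `t` (an event time exactly at
`t` counts to the upper side).  The window is `[min L, max U]`, so it holds
exactly the `2m` nearest event times by rank.  Boundary rules: with no event
time below `t` the window starts at 0; beyond the last event time the window
covers the `2m` (or all available) nearest event times below `t` and extends
symmetrically above `t`.  Fewer than `m` neighbors on a side means all
available ones are used.  The default `m = 5` is a practical small-sample
choice; the window then typically spans 10 event times and adapts
automatically to the local density of events, which in survival data is high
early and sparse late — precisely where a fixed bandwidth fails.

Placing the window endpoints *at* the rank-neighbors (rather than using a
symmetric metric half-width) was a deliberate design choice: the set of
jumps inside the window is then a function of event-time ranks alone.
Consequently, for two models fitted on the same training data the window,
and each model's in-window mass, transform consistently under any strictly
increasing time warp, and the *difference* in total smoothed predictive
log-likelihood between the models is exactly invariant (the `−log(window
length)` and `Ĥ(t|x)` terms are rank-determined or common).  A symmetric
metric window loses this exactness because a warp can move extra near-side
event times across the window edge.  The test suite asserts the invariance
to `1e−8` under `t → t²` and `t → log(1+t)`.

**Loss.**  For a test subject `(t, δ, x)`:

* `δ = 0`: the loss is `−Ĥ(t|x)` exactly — no smoothing involved.
* `δ = 1`: the loss is `log(max(ĥ_s(t|x), ε)) − Ĥ(t|x)` with floor
  `ε = 10⁻¹²`.  The floor only binds when the predicted in-window mass is
  zero or negative (possible for additive-hazards predictions); floor hits
  are counted and reported on the cross-validation result.

The loss is always finite, and every test subject's value depends only on
the training fold and that subject — never on other test-set members.

**Model specializations.**

* Cox: `ĥ_s(t|x) = e^{x'β̂} ĥ₀ₛ(t)`, so only the Breslow baseline is
  smoothed.
* Gamma frailty: the smoother is applied to the *marginal* cumulative hazard
  `H_m(t|x) = log(1 + θ̂ Ĥ(t|x)) / θ̂`, itself a step function with the
  same jump locations; at `θ̂ = 0` this reduces exactly to the Cox case.
* Additive hazards: the generic path smooths `Ĥ(t|x) = x*' B̂(t)` directly;
  negative increments are preserved and only the log is floored.

## Model fitters

**Cox (`CoxPH`).**  Newton–Raphson on the Breslow partial log-likelihood,
starting at `β = 0`, with step-halving on likelihood decrease.  Convergence
when the maximum absolute score component drops below `1e−8`, with a
fallback stop when the log-likelihood change falls below floating precision
(`1e−13` relative) — necessary at large `n`, where an absolute score
tolerance is unreachable.  Coefficients exceeding 30 in absolute value (at
convergence) or 100 (during iteration) trigger a divergence error: this is
the monotone-likelihood / perfect-separation guard.  Risk-set sums are
reverse cumulative sums over the time-sorted sample, so one fit is
`O(n log n + np)` per Newton step; the CV engine and the frailty EM depend
on this being fast.  Baseline increments are `d(t) / Σ_{j∈R(t)} e^{x_j'β̂}`
at each unique event time.

**Verweij CVPL.**  For subject `i` in test fold `D`, the contribution is
`pl^{(+i)}(β̂(−D)) − pl^{(−D)}(β̂(−D))`, with `pl^{(+i)}` the partial
likelihood of the training fold augmented by subject `i` alone; leave-one-out
is the singleton-fold special case and reproduces the classical definition
exactly.  The difference is evaluated in closed incremental form — add
`w_i = e^{x_i'β̂}` to the risk-set sums of training events at or before
`T_i`, plus the subject's own event term — which the tests verify against a
literal two-evaluation oracle to `1e−10`.  K-fold contributions use the
augmented-training form rather than the full-data partial likelihood so that
no contribution depends on other test-fold members.

**Gamma frailty (`GammaFrailtyPH`).**  Hazard `Z h₀(t) e^{x'β}` with
subject-level frailty `Z ~ Gamma(mean 1, variance θ)`; marginal survival
`(1 + θĤ)^{−1/θ}`.  For fixed `θ`, the EM alternates posterior frailty
means `z_i = (1/θ + δ_i)/(1/θ + Ĥ(T_i|x_i))` with an offset-`log z` Cox
fit and a `z`-weighted Breslow baseline, and is monotone in the marginal
log-likelihood.  Because plain EM converges linearly with rate approaching 1
as `θ` grows, two accelerations are applied that leave the fixed point
untouched: the M-step takes a few warm-started Newton ascent steps rather
than iterating to convergence (a generalized EM), and cycles are
extrapolated SQUAREM-style on the frailty-mean vector, keeping an
accelerated jump only if the marginal log-likelihood does not decrease (so
the recorded trace stays monotone).  Iteration stops when the
Aitken-extrapolated remaining gain drops below `em_tol` (default `1e−6`),
not merely the last gain.  `θ` is
profiled by bounded Brent search on `log(θ + 0.01)` over `[0, 20]`
(`xatol = 1e−5`), with the boundary `θ = 0` (a plain Cox fit) always
evaluated explicitly; boundary estimates are legitimate and occur with
appreciable probability when the data carry no frailty.  Parameter recovery
(`θ = 2`, `n = 2000`) and boundary recovery (`θ = 0`) are exercised in the
tests.

**Additive hazards (`AalenAdditive`).**  At each event time the increment of
the cumulative regression function solves the (optionally ridge-penalized)
least-squares problem on the at-risk design `X(t)` (rows `Y_i(t)·(1, x_i')`):
`dB̂(t) = (X(t)'X(t) + λI)⁻¹ X(t)' dN(t)`.  When `X(t)` is rank deficient —
smallest singular value of `X(t)` itself below `1e−10` times the largest —
the increment is set to zero, for `λ = 0` and `λ > 0` alike.  The rank test
runs on `X(t)`, not `X(t)'X(t)`, whose squared spectrum would push the
threshold below floating precision.  Ridge is applied to the raw
(unstandardized) design, which defines the meaning of `λ`; by default all
columns including the intercept are penalized, with a flag to exempt the
intercept.  Predicted cumulative hazards `x*'B̂(t)` may decrease — the known
defect of the OLS estimator, mitigated but not removed by ridge — and are
deliberately left unrepaired; only the log of the smoothed hazard is floored.

## Cross-validation, comparator losses, selection

`kfold_split` partitions subjects into `K` folds of near-equal size from a
seeded permutation.  `cv_evaluate` fits the candidate on each training fold
and sums per-subject losses; smoothing windows always come from the training
fold's event times.  The fold standard error of a total is
`sd(fold sums) · √K`.

The IPCW Brier score at horizon `t*` weighs each test subject by the inverse
Kaplan–Meier censoring-survival estimate `Ĝ` from the *training* fold:
events at or before `t*` contribute `Ŝ(t*|x)² / Ĝ(T−)`, subjects still at
risk contribute `(1 − Ŝ(t*|x))² / Ĝ(t*)`, subjects censored before `t*`
contribute zero.  The default `t*` is the median observed follow-up time of
the full sample (the Kaplan–Meier median is an alternative a caller can pass
explicitly).  Subjects needing a zero `Ĝ` are dropped and counted.  The
integrated Brier score integrates the same contributions by the trapezoid
rule over the training event times from 0 to the largest one, normalized by
that length.  The implementation agrees with scikit-survival's Brier score
to machine precision on shared conventions (verified in the tests).

`select_model` normalizes loss direction (log-likelihoods: larger is better;
Brier-type: smaller), picks the best-scoring candidate (ties to the more
parsimonious), and applies the one-standard-error rule: the most
parsimonious candidate whose score is within one fold-SE of the best.

## Synthetic-data generators and study conditions

The generators emulate two study designs, which are also the package's
fixtures:

* **Variable selection**: `n = 500`, four independent `N(0,1)` covariates,
  true hazard `e^{x'β}` with constant baseline 1 (exponential latent times),
  uniform `[0, C]` censoring with `C` calibrated so 40% of subjects are
  censored.  Default `β = (1, 0, 0, 0)`; all 16 covariate subsets compete
  under 10-fold CV.
* **Frailty vs Cox**: one covariate, `β = 0.8`, latent `Gamma(1/θ, θ)`
  frailty multiplying the hazard, again ~40% calibrated censoring
  (recalibrated per `θ`, since frailty changes the marginal event-time
  distribution; the generator reduces bit-exactly to the Cox generator at
  `θ = 0`).

Calibration solves `E[min(T̃/C, 1)] = target` — the exact censoring
probability given the latent times — by Brent's method on a fixed
100,000-draw calibration sample, making the bound deterministic given the
seed and the realized censoring fraction accurate to well under a
percentage point.

In the frailty-vs-Cox study the preferred model per replicate is the one
with the larger CV loss score.  When every fold estimates `θ̂ = 0` the two
models are identical and the losses tie exactly; a tie carries no preference
information, so it is broken by a seeded fair coin — for indistinguishable
models the expected selection balance is 50/50.  This matters only at (or
extremely near) `θ = 0`, where the selection frequency is dominated by how
an implementation resolves the boundary; away from it ties essentially never
occur.

What the generators do *not* emulate: tied or discretized recording times,
covariate-dependent or informative censoring, time-varying covariates or
effects, model misspecification beyond the frailty term.  Passing tests
therefore demonstrate correctness of the estimators and the loss machinery
under clean sampling conditions, not robustness to those real-data features.

## Problem sizes and numerical choices

Monte-Carlo scale was chosen for a single-CPU workstation: the
frailty-vs-Cox study runs `M = 200` replicates per frailty variance
(`θ ∈ {0, 2, 5}` in the acceptance script, ~2 minutes each) and the
variable-selection study `M = 100`; binomial Monte-Carlo error at these
sizes (±3–10 percentage points, 3-SE) is the relevant comparison tolerance.
Other defaults: Newton tolerance `1e−8` / 50 iterations; EM tolerance `1e−6`
(Aitken-extrapolated) / 2000 iterations; `θ` search bound 20; hazard floor
`1e−12`; additive rank threshold `1e−10`; ridge-path grid 30 points over
`log₁₀λ ∈ [0, 3]`.  All randomness flows through `numpy.random.Generator`
objects spawned from a single seed; every dataset, fold assignment and study
table is bit-exactly reproducible.

## Known limitations

* Only the uniform kernel and a global neighbor count `m` are implemented;
  covariate-dependent bandwidths and asymptotic bandwidth theory are out of
  scope.
* The CVPL exists only for Cox models (it needs a partial likelihood); the
  engine refuses it for other estimators.
* The frailty model is univariate (one subject per frailty); shared/clustered
  frailty and non-gamma frailty distributions are not supported.
* Left truncation, interval censoring, time-dependent covariates and
  competing risks are out of scope.
* The constrained-likelihood repair of decreasing additive-hazards curves is
  not implemented; negative increments are handled only through the floor in
  the loss.
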