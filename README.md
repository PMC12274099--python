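# smoothlik

Smoothed predictive log-likelihood for validating semi- and nonparametric
survival models.

## The problem

Semiparametric survival estimators — Cox proportional hazards, gamma-frailty
models, Aalen's additive hazards — return *step-function* survival curves
`Ŝ(t|x)`, with jumps only at event times observed in the training data.  For
a test subject the natural scoring rule is the predictive log-likelihood

```
L(Ŝ(·|x), t, δ) = δ log ĥ(t|x) − Ĥ(t|x),
```

where `Ĥ = −log Ŝ` is the cumulative hazard and `ĥ` its derivative.  But a
step function has `ĥ(t) = 0` almost everywhere, so any test subject whose
event falls at a new time point scores `−∞` — for every model, making the
loss useless.  The classical fix, the Verweij–van Houwelingen cross-validated
partial likelihood (CVPL), exists only for Cox models, and it quietly borrows
risk-set information from the test subject.

`smoothlik` implements a general fix: estimate the hazard by smoothing the
predicted cumulative hazard with a uniform kernel whose window reaches to the
`m`-th training event time on each side of the query time (default `m = 5`),

```
ĥ_s(t|x) = ( mass of dĤ(·|x) inside the window ) / ( window length ).
```

Because the window is tied to event-time *ranks*, comparisons between models
fitted on the same training data are exactly invariant under any strictly
increasing warp of the time axis — the same invariance the underlying
estimators have.  The loss applies unchanged to Cox fits (only the Breslow
baseline needs smoothing), to gamma-frailty fits (smooth the marginal
cumulative hazard `H_m = log(1 + θĤ)/θ`), and to ridge-penalized additive
hazards fits (where no partial likelihood exists at all).

The package provides, as scikit-learn-style estimators and thin functional
wrappers:

* `CoxPH` — Newton–Raphson partial-likelihood fit, Breslow baseline, CVPL;
* `GammaFrailtyPH` — EM fit of the univariate gamma-frailty model with the
  frailty variance profiled over `[0, θ_max]`;
* `AalenAdditive` — Aalen's OLS estimator and its ridge-penalized variant;
* `cv_evaluate` / `select_model` — K-fold cross-validation under the smoothed
  likelihood, CVPL, IPCW Brier score and integrated Brier score, with
  min-error and one-standard-error selection rules;
* `simulate_*` / `run_simulation1` / `run_simulation2` — calibrated synthetic
  data generators and the two Monte-Carlo model-selection studies.

## Worked example

Does a sample carry a frailty term?  Simulate 500 subjects from a
gamma-frailty model (`β = 0.8`, frailty variance `θ = 2`, ~40% censoring),
then compare a Cox and a frailty model by 10-fold CV smoothed likelihood:

```python
import smoothlik as sl

cfg = sl.SimConfig(n=500, beta=(0.8,), theta=2.0, seed=42)
data = sl.simulate_frailty_data(cfg)

folds = sl.kfold_split(data.n, 10, seed=0)
cox = sl.cv_evaluate(sl.CoxPH(), data.X, data.y,
                     losses="smoothed_loglik", folds=folds)
fr = sl.cv_evaluate(sl.GammaFrailtyPH(), data.X, data.y,
                    losses="smoothed_loglik", folds=folds)
print(f"Cox     CV smoothed log-likelihood: {cox.total:.2f} (fold SE {cox.fold_se:.2f})")
print(f"Frailty CV smoothed log-likelihood: {fr.total:.2f} (fold SE {fr.fold_se:.2f})")

report = sl.select_model({"cox": cox, "frailty": fr}, {"cox": 0, "frailty": 1})
print("min-error winner:", report.winner_min, "| one-SE winner:", report.winner_1se)

fit = sl.fit_gamma_frailty(data)
print(f"full-data frailty fit: beta = {fit.coef_[0]:.3f}, theta = {fit.theta_:.3f}")
```

prints

```
Cox     CV smoothed log-likelihood: -537.78 (fold SE 16.45)
Frailty CV smoothed log-likelihood: -529.49 (fold SE 18.13)
min-error winner: frailty | one-SE winner: cox
full-data frailty fit: beta = 0.959, theta = 2.456
```

The frailty model predicts this sample better by 8.3 log-likelihood points
(higher is better), so the min-error rule selects it; the more conservative
one-SE rule, which demands an advantage exceeding one fold-SE, falls back to
the more parsimonious Cox model here.  The full-data fit recovers the
generating parameters.

The same machinery runs from a shell, e.g.

```sh
smoothlik simulate --kind frailty --theta 2 --beta 0.8 --n 500 --seed 42 --out data.csv
smoothlik select data.csv --candidates cox-vs-frailty --k 10 --out selection.csv
smoothlik ridge-path data.csv --grid-log10 0:3:30 --out path.csv
```

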