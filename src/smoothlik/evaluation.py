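"""Out-of-sample loss functions and the cross-validation / selection engine.

Losses (per test subject, aggregated by summation over folds):

* ``smoothed_loglik`` -- the smoothed predictive log-likelihood
  ``delta log h_s(t|x) - H(t|x)``; the smoothing windows are always built
  from the TRAINING fold's event times, so a test subject's loss depends on
  the training fold and that subject only (no test-set leakage).
* ``cvpl`` -- Verweij--van Houwelingen cross-validated partial
  log-likelihood (Cox models only; no other model has a partial likelihood).
* ``brier`` -- inverse-probability-of-censoring-weighted Brier score at a
  fixed horizon t* (default: median observed follow-up time of the full
  sample); censoring distribution estimated on the training fold.
* ``ibs`` -- integrated Brier score, trapezoid rule over the training event
  times from 0 to the largest one, normalized by the integration length.

Log-likelihood losses are better when LARGER, Brier-type losses when
smaller; :class:`CVResult` records the direction and
:func:`select_model` normalizes it, implementing both the minimum-error rule
and the one-standard-error rule (most parsimonious candidate within one
standard error of the best, the SE being sd(fold sums) * sqrt(K)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.base import clone

from . import cox as _cox
from .core import StepFunction, SurvivalData, as_survival_arrays, km_censoring
from .cox import CoxPH
from .smoothing import SmootherConfig, nn_windows

__all__ = [
    "CVResult",
    "SelectionReport",
    "kfold_split",
    "cv_evaluate",
    "brier_score",
    "integrated_brier",
    "select_model",
]

logger = logging.getLogger(__name__)

LOSS_DIRECTION = {"smoothed_loglik": "higher", "cvpl": "higher",
                  "brier": "lower", "ibs": "lower"}


@dataclass
class CVResult:
    """Cross-validated loss: per-subject values, fold sums, total, fold SE."""

    loss: str
    per_subject: np.ndarray
    fold_index: np.ndarray          # fold id of each subject
    K: int
    seed: int | None
    direction: str                  # 'higher' or 'lower' is better
    n_floor_hits: int = 0
    n_dropped: int = 0
    per_fold_sum: np.ndarray = field(init=False)
    total: float = field(init=False)
    fold_se: float = field(init=False)

    def __post_init__(self):
        sums = np.array([self.per_subject[self.fold_index == k].sum()
                         for k in range(self.K)])
        self.per_fold_sum = sums
        self.total = float(self.per_subject.sum())
        # SE of the total from the spread of the K fold sums
        self.fold_se = float(np.std(sums, ddof=1) * np.sqrt(self.K)) if self.K > 1 else 0.0

    @property
    def score(self) -> float:
        """Total on a larger-is-better scale."""
        return self.total if self.direction == "higher" else -self.total


@dataclass
class SelectionReport:
    """Candidate losses plus winners under the min-error and one-SE rules."""

    candidates: list
    results: Mapping
    winner_min: object
    winner_1se: object
    parsimony: Mapping


def kfold_split(n: int, K: int, seed) -> list[np.ndarray]:
    """Deterministic partition of ``{0..n-1}`` into K folds of near-equal size."""
    if not 2 <= K <= n:
        raise ValueError("need 2 <= K <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, K)]


def _cumhaz_grid(est, X, grid):
    """(n_X, n_grid) cumulative hazards; marginal for frailty models."""
    if hasattr(est, "risk_score") and hasattr(est, "baseline_hazard_"):
        w = est.risk_score(X)
        base_cum = np.concatenate(([0.0], est.baseline_hazard_.cumulative))
        idx = np.searchsorted(est.event_times_, grid, side="right")
        H = np.outer(w, base_cum[idx])
        if hasattr(est, "_marginal_transform"):
            H = est._marginal_transform(H)
        return H
    cum = np.empty((X.shape[0], len(grid)))
    for i, sf in enumerate(est.predict_cumulative_hazard(X)):
        cum[i] = sf(np.asarray(grid, float))
    return cum


def _smoothed_losses(est, X_te, t_te, d_te, smoother):
    """Vectorized smoothed predictive log-likelihood per test subject."""
    H_t = est.cumulative_hazard_at(X_te, t_te)
    loss = -H_t
    ev = np.flatnonzero(d_te == 1)
    floor_hits = 0
    if ev.size:
        lo, hi = nn_windows(est.event_times_, t_te[ev], smoother.m)
        mass = (est.cumulative_hazard_at(X_te[ev], hi, side="right")
                - est.cumulative_hazard_at(X_te[ev], lo, side="left"))
        hs = mass / (hi - lo)
        floored = hs < smoother.hazard_floor
        floor_hits = int(floored.sum())
        loss[ev] += np.log(np.maximum(hs, smoother.hazard_floor))
    return loss, floor_hits


def _ipcw_weights(G: StepFunction, time, event, t_star):
    """Per-subject IPCW weight for the Brier score at horizon ``t_star``.

    Events before/at t* weigh 1/G(T-); survivors weigh 1/G(t*); subjects
    censored before t* weigh 0.  Subjects whose required G is 0 get weight 0
    and are counted as dropped.
    """
    w = np.zeros(time.size)
    dropped = 0
    had_event = (time <= t_star) & (event == 1)
    at_risk = time > t_star
    G_left = np.asarray(G(time, side="left"), dtype=float)
    G_star = float(G(t_star))
    for i in np.flatnonzero(had_event):
        if G_left[i] > 0:
            w[i] = 1.0 / G_left[i]
        else:
            dropped += 1
    if np.any(at_risk):
        if G_star > 0:
            w[at_risk] = 1.0 / G_star
        else:
            dropped += int(at_risk.sum())
    return w, had_event, at_risk, dropped


def _brier_contributions(S_star, time, event, t_star, G):
    w, had_event, at_risk, dropped = _ipcw_weights(G, time, event, t_star)
    contrib = np.zeros(time.size)
    contrib[had_event] = w[had_event] * S_star[had_event] ** 2
    contrib[at_risk] = w[at_risk] * (1.0 - S_star[at_risk]) ** 2
    return contrib, dropped


def cv_evaluate(estimator, X, y, losses="smoothed_loglik", K: int = 10,
                seed=0, folds=None, smoother: SmootherConfig | None = None,
                t_star=None):
    """K-fold cross-validated losses of one model specification.

    Parameters
    ----------
    estimator : CoxPH, GammaFrailtyPH or AalenAdditive
        Unfitted estimator; cloned and refitted on each training fold.
    X, y : array-likes
        Covariates and outcome (structured array, ``(time, event)`` pair, or
        :class:`SurvivalData` as ``y`` with ``X=None``).
    losses : str or sequence of str
        Any of ``smoothed_loglik``, ``cvpl``, ``brier``, ``ibs``; a sequence
        shares the per-fold fits across losses.
    K, seed, folds
        Fold count and RNG seed, or explicit fold index arrays (overrides
        ``K``/``seed``; used to share folds across candidate models).
    smoother : SmootherConfig
        Settings for the smoothed likelihood (default m=5).
    t_star : float
        Brier horizon; default median observed follow-up time of ``y``.

    Returns
    -------
    CVResult or dict[str, CVResult]
        A dict when ``losses`` is a sequence.
    """
    single = isinstance(losses, str)
    loss_list = [losses] if single else list(losses)
    for name in loss_list:
        if name not in LOSS_DIRECTION:
            raise ValueError(f"unknown loss {name!r}")
    if isinstance(y, SurvivalData) and X is None:
        X = y.X
    time, event = as_survival_arrays(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = time.size
    smoother = smoother or SmootherConfig()
    if folds is None:
        folds = kfold_split(n, K, seed)
    else:
        folds = [np.asarray(f, dtype=np.int64) for f in folds]
        K = len(folds)
    if t_star is None:
        t_star = float(np.median(time))

    fold_index = np.empty(n, dtype=np.int64)
    for k, idx in enumerate(folds):
        fold_index[idx] = k

    per_subject = {name: np.zeros(n) for name in loss_list}
    floor_hits = dict.fromkeys(loss_list, 0)
    dropped = dict.fromkeys(loss_list, 0)

    model_losses = [name for name in loss_list if name != "cvpl"]
    if "cvpl" in loss_list:
        if not isinstance(estimator, CoxPH):
            raise ValueError("cvpl requires a Cox model "
                             "(it relies on the partial likelihood)")
        data = SurvivalData(time, event, X)
        per_subject["cvpl"] = _cox.cvpl_contributions(data, folds)

    if model_losses:
        need_struct = np.empty(n, dtype=[("event", "?"), ("time", "<f8")])
        need_struct["event"] = event.astype(bool)
        need_struct["time"] = time
        for k, te in enumerate(folds):
            tr_mask = np.ones(n, dtype=bool)
            tr_mask[te] = False
            tr = np.flatnonzero(tr_mask)
            est = clone(estimator).fit(X[tr], need_struct[tr])
            t_te, d_te, X_te = time[te], event[te], X[te]
            if "smoothed_loglik" in model_losses:
                loss, hits = _smoothed_losses(est, X_te, t_te, d_te, smoother)
                per_subject["smoothed_loglik"][te] = loss
                floor_hits["smoothed_loglik"] += hits
            if "brier" in model_losses or "ibs" in model_losses:
                G = km_censoring(SurvivalData(time[tr], event[tr]))
            if "brier" in model_losses:
                S_star = est.survival_at(X_te, np.full(te.size, t_star))
                contrib, ndrop = _brier_contributions(S_star, t_te, d_te,
                                                      t_star, G)
                per_subject["brier"][te] = contrib
                dropped["brier"] += ndrop
            if "ibs" in model_losses:
                contrib, ndrop = _ibs_contributions(est, X_te, t_te, d_te, G)
                per_subject["ibs"][te] = contrib
                dropped["ibs"] += ndrop
    if any(floor_hits.values()) or any(dropped.values()):
        logger.info("cv_evaluate: floor hits %s, dropped %s (seed=%s)",
                    floor_hits, dropped, seed)

    out = {name: CVResult(loss=name, per_subject=per_subject[name],
                          fold_index=fold_index, K=K, seed=seed,
                          direction=LOSS_DIRECTION[name],
                          n_floor_hits=floor_hits[name],
                          n_dropped=dropped[name])
           for name in loss_list}
    return out[loss_list[0]] if single else out


def _ibs_contributions(est, X_te, t_te, d_te, G: StepFunction):
    """Per-subject integrated Brier contribution over the training grid."""
    grid = np.concatenate(([0.0], est.event_times_))
    t_max = grid[-1]
    S = np.exp(-_cumhaz_grid(est, X_te, grid))         # (n_te, n_grid)
    G_left = np.asarray(G(t_te, side="left"), dtype=float)
    G_grid = np.asarray(G(grid), dtype=float)
    dropped = int(np.sum((d_te == 1) & (G_left <= 0)))
    w_event = np.where(G_left > 0, 1.0 / np.where(G_left > 0, G_left, 1.0), 0.0)
    w_grid = np.where(G_grid > 0, 1.0 / np.where(G_grid > 0, G_grid, 1.0), 0.0)
    had_event = ((t_te[:, None] <= grid[None, :]) & (d_te[:, None] == 1))
    at_risk = t_te[:, None] > grid[None, :]
    integrand = (had_event * w_event[:, None] * S ** 2
                 + at_risk * w_grid[None, :] * (1.0 - S) ** 2)
    return np.trapezoid(integrand, grid, axis=1) / t_max, dropped


def brier_score(pred_surv_at_tstar, test_data: SurvivalData, t_star: float,
                G: StepFunction) -> float:
    """IPCW Brier score at horizon ``t_star`` (mean over test subjects).

    ``pred_surv_at_tstar`` is an array of predicted survival probabilities
    S(t*|x_i), or a list of survival-type step functions to evaluate there.
    ``G`` is the censoring-survival estimate from the TRAINING data.
    Subjects censored before t* contribute 0; subjects whose required G
    value is 0 are dropped (logged).
    """
    S_star = _as_surv_probs(pred_surv_at_tstar, t_star)
    contrib, dropped = _brier_contributions(S_star, test_data.time,
                                            test_data.event, t_star, G)
    if dropped:
        logger.warning("brier_score: dropped %d subjects with G=0", dropped)
    denom = test_data.n - dropped
    if denom <= 0:
        raise ValueError("no usable subjects for the Brier score")
    return float(contrib.sum() / denom)


def integrated_brier(pred_curves, test_data: SurvivalData, G: StepFunction,
                     grid) -> float:
    """Integrated IPCW Brier score over ``grid`` (training event times).

    Trapezoid rule from 0 to the largest grid time, normalized by that
    length; ``pred_curves`` is a list of survival-type step functions.
    """
    grid = np.concatenate(([0.0], np.asarray(grid, dtype=float)))
    t_max = grid[-1]
    scores = np.array([
        _mean_brier_at(pred_curves, test_data, t, G) for t in grid
    ])
    return float(np.trapezoid(scores, grid) / t_max)


def _mean_brier_at(pred_curves, test_data, t, G):
    if t == 0.0:
        return 0.0
    return brier_score(pred_curves, test_data, t, G)


def _as_surv_probs(pred, t_star):
    if isinstance(pred, np.ndarray) and pred.dtype != object:
        return pred.astype(float)
    return np.array([float(sf(t_star)) for sf in pred])


def select_model(results: Mapping, parsimony: Mapping, rule: str | None = None):
    """Pick winners among candidate :class:`CVResult` mappings.

    ``parsimony`` maps candidate id to a sortable complexity key (smaller =
    more parsimonious; e.g. covariate count).  The min-error rule picks the
    best score (larger-is-better after direction normalization), breaking
    ties toward the more parsimonious candidate; the one-SE rule picks the
    most parsimonious candidate whose score is within one fold-SE of the
    best.  Returns a :class:`SelectionReport` (or the winning id when
    ``rule`` is given).
    """
    if not results:
        raise ValueError("no candidates")
    ids = list(results)
    if set(parsimony) < set(ids):
        raise ValueError("parsimony must cover all candidates")
    best = max(ids, key=lambda c: results[c].score)
    # parsimony tie-break on exactly equal scores
    for c in ids:
        if results[c].score == results[best].score \
                and _rank(parsimony[c]) < _rank(parsimony[best]):
            best = c
    threshold = results[best].score - results[best].fold_se
    eligible = [c for c in ids if results[c].score >= threshold]
    one_se = min(eligible, key=lambda c: (_rank(parsimony[c]), -results[c].score))
    report = SelectionReport(candidates=ids, results=dict(results),
                             winner_min=best, winner_1se=one_se,
                             parsimony=dict(parsimony))
    if rule is None:
        return report
    if rule == "min":
        return best
    if rule in ("one_se", "1se"):
        return one_se
    raise ValueError(f"unknown rule {rule!r}")


def _rank(key):
    return key
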