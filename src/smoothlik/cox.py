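"""Cox proportional hazards: partial likelihood, Breslow baseline, CVPL.

The fitter is a plain Newton--Raphson maximizer of the Breslow-tie partial
log-likelihood

    pl(beta) = sum_{j: delta_j = 1} [ x_j' beta - log sum_{k in R(t_j)} e^{x_k' beta} ],

with the baseline hazard increment profiled out at each event time t as

    h0(t; beta) = d(t) / sum_{j in R(t)} e^{x_j' beta}            (Breslow).

Risk-set sums are computed by reverse cumulative sums over the time-sorted
sample, so a fit costs O(n log n + n p per Newton step); the cross-validation
engine and the gamma-frailty EM rely on this being fast.

The module also implements the Verweij--van Houwelingen cross-validated
partial log-likelihood (CVPL): for a test subject i and training estimate
beta(-D) of the fold excluding i,

    cvpl_i = pl^{(+i)}(beta(-D)) - pl^{(-D)}(beta(-D)),

where pl^{(+i)} is the partial likelihood of the training set augmented with
subject i alone.  For singleton folds this is exactly the leave-one-out CVPL.
Each contribution depends only on the training fold and subject i, never on
other test-set members.  The difference is evaluated in closed incremental
form (adding w_i = e^{x_i' beta} to the affected risk-set sums) rather than by
two full partial-likelihood evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import StepFunction, SurvivalData, as_survival_arrays

__all__ = [
    "CoxPH",
    "ConvergenceError",
    "fit_cox",
    "partial_loglik",
    "predict_cumhaz",
    "cvpl_verweij",
    "cvpl_contributions",
]


class ConvergenceError(RuntimeError):
    """Raised when Newton--Raphson or the frailty EM fails to converge.

    Carries the last iterate in ``last_iterate`` (and an iteration trace when
    available) so callers can inspect the failure.
    """

    def __init__(self, message, last_iterate=None, trace=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.trace = trace


# ---------------------------------------------------------------------------
# internal prepared representation (time-sorted, tie groups resolved once)
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    time: np.ndarray          # sorted ascending
    event: np.ndarray         # bool, sorted with time
    X: np.ndarray             # (n, p), sorted with time
    order: np.ndarray         # original index of each sorted row
    group_first: np.ndarray   # first sorted index of each row's tie group
    uniq_event_times: np.ndarray
    ev_group_first: np.ndarray  # risk-set start index per unique event time
    d: np.ndarray               # event multiplicity per unique event time
    ev_rows: np.ndarray         # sorted row indices of events

    @property
    def n(self):
        return self.time.size

    @property
    def p(self):
        return self.X.shape[1]


def _prepare(time, event, X) -> _Prepared:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    Xs = X[order]
    group_first = np.searchsorted(t, t, side="left")
    ev_rows = np.flatnonzero(e)
    if ev_rows.size == 0:
        raise ValueError("data contains no events")
    ev_times = t[ev_rows]
    uniq, first_in_ev = np.unique(ev_times, return_index=True)
    d = np.diff(np.append(first_in_ev, ev_times.size)).astype(float)
    ev_group_first = group_first[ev_rows[first_in_ev]]
    return _Prepared(t, e, Xs, order, group_first, uniq, ev_group_first, d, ev_rows)


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _pl_value(prep: _Prepared, beta: np.ndarray, offset=None) -> float:
    eta = prep.X @ beta if prep.p else np.zeros(prep.n)
    if offset is not None:
        eta = eta + offset
    w = np.exp(eta)
    S0 = _revcumsum(w)[prep.ev_group_first]
    return float(eta[prep.ev_rows].sum() - prep.d @ np.log(S0))


def _pl_score_info(prep: _Prepared, beta: np.ndarray, offset=None):
    """Partial log-likelihood value, score and observed information."""
    eta = prep.X @ beta if prep.p else np.zeros(prep.n)
    if offset is not None:
        eta = eta + offset
    w = np.exp(eta)
    S0 = _revcumsum(w)[prep.ev_group_first]
    ll = float(eta[prep.ev_rows].sum() - prep.d @ np.log(S0))
    if prep.p == 0:
        return ll, np.zeros(0), np.zeros((0, 0))
    wX = w[:, None] * prep.X
    S1 = _revcumsum(wX)[prep.ev_group_first]            # (K, p)
    m1 = S1 / S0[:, None]
    score = prep.X[prep.ev_rows].sum(axis=0) - prep.d @ m1
    S2 = _revcumsum(np.einsum("ij,ik->ijk", wX, prep.X))[prep.ev_group_first]
    m2 = S2 / S0[:, None, None]
    info = np.einsum("k,kij->ij", prep.d, m2 - np.einsum("ki,kj->kij", m1, m1))
    return ll, score, info


def _newton(prep: _Prepared, offset=None, beta0=None, tol: float = 1e-8,
            max_iter: int = 50, best_effort: bool = False):
    """Maximize the partial likelihood; returns (beta, loglik, n_iter).

    ``best_effort=True`` returns the last iterate after ``max_iter`` ascent
    steps instead of raising (used by the generalized-EM M-step, which only
    needs to increase the offset partial likelihood, not maximize it).
    """
    p = prep.p
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    if p == 0:
        return beta, _pl_value(prep, beta, offset), 0
    ll, score, info = _pl_score_info(prep, beta, offset)
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        # primary criterion: score ~ 0; fallback: the likelihood has stopped
        # moving at floating precision (the score cannot shrink further)
        if np.max(np.abs(score)) < tol or \
                abs(ll - ll_prev) < 1e-13 * (abs(ll) + 1.0):
            if np.max(np.abs(beta)) > 30.0:
                raise ConvergenceError(
                    "diverging coefficients (monotone likelihood / separation)",
                    last_iterate=beta)
            return beta, ll, it - 1
        ll_prev = ll
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # flat/degenerate information
            raise ConvergenceError("singular information matrix",
                                   last_iterate=beta) from exc
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _pl_value(prep, cand, offset)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 100.0:
            raise ConvergenceError(
                "diverging coefficients (monotone likelihood / separation)",
                last_iterate=beta)
        ll, score, info = _pl_score_info(prep, beta, offset)
    if best_effort or np.max(np.abs(score)) < tol \
            or abs(ll - ll_prev) < 1e-13 * (abs(ll) + 1.0):
        return beta, ll, max_iter
    raise ConvergenceError(
        f"Newton-Raphson did not converge in {max_iter} iterations",
        last_iterate=beta)


def _breslow(prep: _Prepared, beta: np.ndarray, offset=None, weights=None):
    """Breslow baseline increments d_k / S0_k at the unique event times.

    ``weights`` multiplies each subject's risk weight (used by the frailty
    EM, where the posterior frailty mean enters the risk-set sums).
    """
    eta = prep.X @ beta if prep.p else np.zeros(prep.n)
    if offset is not None:
        eta = eta + offset
    w = np.exp(eta)
    if weights is not None:
        w = w * weights
    S0 = _revcumsum(w)[prep.ev_group_first]
    return prep.d / S0, S0


def _cumhaz_index(prep: _Prepared, t, side="right"):
    """Number of unique event times <= t (or < t for side='left')."""
    return np.searchsorted(prep.uniq_event_times, t, side=side)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CoxPH(BaseEstimator):
    """Cox proportional hazards model with Breslow baseline hazard.

    Parameters
    ----------
    tol : float
        Newton--Raphson convergence tolerance on the maximum absolute score
        component.
    max_iter : int
        Maximum Newton iterations before a :class:`ConvergenceError`.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Maximum partial-likelihood estimate ``beta_hat``.
    baseline_hazard_ : StepFunction
        Breslow cumulative baseline hazard with jumps at the unique training
        event times (increments strictly positive).
    event_times_ : ndarray
        Sorted unique training event times.
    log_partial_likelihood_ : float
        Maximized partial log-likelihood.
    n_iter_ : int
        Newton iterations used.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        time, event = as_survival_arrays(y)
        X = self._check_X(X, n=time.size)
        prep = _prepare(time, event, X)
        beta, ll, n_iter = _newton(prep, tol=self.tol, max_iter=self.max_iter)
        incr, _ = _breslow(prep, beta)
        self.coef_ = beta
        self.n_iter_ = n_iter
        self.log_partial_likelihood_ = ll
        self.event_times_ = prep.uniq_event_times
        self.baseline_hazard_ = StepFunction(prep.uniq_event_times, incr)
        self._prep = prep
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check_X(X, n=None, p=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-d array")
        if n is not None and X.shape[0] != n:
            raise ValueError("X row count does not match outcome length")
        if p is not None and X.shape[1] != p:
            raise ValueError(f"X has {X.shape[1]} columns, expected {p}")
        return X

    def _validate_for_predict(self, X):
        if not hasattr(self, "coef_"):
            raise ValueError("estimator is not fitted")
        return self._check_X(X, p=self.n_features_in_)

    def risk_score(self, X) -> np.ndarray:
        """``w = exp(x' beta_hat)`` per row of ``X``."""
        X = self._validate_for_predict(X)
        return np.exp(X @ self.coef_)

    def predict_cumulative_hazard(self, X):
        """Per-subject predicted cumulative hazard ``H(t|x)`` step functions."""
        w = self.risk_score(X)
        base_t = self.baseline_hazard_.times
        base_i = self.baseline_hazard_.increments
        return [StepFunction(base_t, wi * base_i) for wi in w]

    def predict_survival_function(self, X):
        """``S(t|x) = exp(-H(t|x))`` as survival-type step functions."""
        curves = []
        for H in self.predict_cumulative_hazard(X):
            surv = np.exp(-H.cumulative)
            curves.append(StepFunction(H.times,
                                       np.diff(np.concatenate(([1.0], surv))),
                                       initial=1.0))
        return curves

    def cumulative_hazard_at(self, X, t, side: str = "right") -> np.ndarray:
        """Paired evaluation ``H(t_i | x_i)`` for rows of ``X`` and times ``t``."""
        w = self.risk_score(X)
        base_cum = np.concatenate(([0.0], self.baseline_hazard_.cumulative))
        idx = np.searchsorted(self.event_times_, np.asarray(t, float), side=side)
        return w * base_cum[idx]

    def survival_at(self, X, t, side: str = "right") -> np.ndarray:
        return np.exp(-self.cumulative_hazard_at(X, t, side=side))


# ---------------------------------------------------------------------------
# functional wrappers on SurvivalData
# ---------------------------------------------------------------------------

def fit_cox(data: SurvivalData, tol: float = 1e-8, max_iter: int = 50) -> CoxPH:
    """Fit a :class:`CoxPH` on a :class:`SurvivalData` sample."""
    return CoxPH(tol=tol, max_iter=max_iter).fit(data.X, data.y)


def partial_loglik(data: SurvivalData, beta) -> float:
    """Breslow-tie Cox partial log-likelihood at a given coefficient vector."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size != data.covariates.shape[1]:
        raise ValueError("beta dimension does not match covariates")
    prep = _prepare(data.time, data.event, data.covariates)
    return _pl_value(prep, beta)


def predict_cumhaz(fit: CoxPH, x) -> StepFunction:
    """Predicted cumulative-hazard step function for one covariate vector."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return fit.predict_cumulative_hazard(x[None, :])[0]


def cvpl_contributions(data: SurvivalData, folds=None, tol: float = 1e-8,
                       max_iter: int = 50) -> np.ndarray:
    """Per-subject Verweij--van Houwelingen CVPL contributions.

    ``folds`` is a sequence of disjoint test-index arrays covering all
    subjects; ``None`` means leave-one-out.  Subject i's contribution is
    ``pl^{(+i)}(beta(-D)) - pl^{(-D)}(beta(-D))`` with D the fold containing
    i, so it never depends on other members of the test fold.
    """
    n = data.n
    if folds is None:
        folds = [np.array([i]) for i in range(n)]
    out = np.empty(n)
    seen = np.zeros(n, dtype=bool)
    for test_idx in folds:
        test_idx = np.asarray(test_idx, dtype=np.int64)
        if np.any(seen[test_idx]):
            raise ValueError("folds must be disjoint")
        seen[test_idx] = True
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        tr = np.flatnonzero(train_mask)
        if data.event[tr].sum() == 0:
            raise ValueError("a fold removes all training events")
        prep = _prepare(data.time[tr], data.event[tr], data.covariates[tr])
        beta, _, _ = _newton(prep, tol=tol, max_iter=max_iter)
        eta = prep.X @ beta if prep.p else np.zeros(prep.n)
        W = _revcumsum(np.exp(eta))                      # risk sums by sorted row
        S0 = W[prep.ev_group_first]                      # at unique event times
        uniq = prep.uniq_event_times
        d = prep.d
        t_i = data.time[test_idx]
        x_i = data.covariates[test_idx]
        eta_i = x_i @ beta if prep.p else np.zeros(t_i.size)
        w_i = np.exp(eta_i)
        # sum over training events with t_k <= T_i of log((S0_k + w_i)/S0_k)
        n_ev = np.searchsorted(uniq, t_i, side="right")
        cum_term = np.zeros(t_i.size)
        for a, (wi, ne) in enumerate(zip(w_i, n_ev)):
            if ne:
                cum_term[a] = d[:ne] @ np.log1p(wi / S0[:ne])
        # own event term: risk set of the augmented sample at T_i
        pos = np.searchsorted(prep.time, t_i, side="left")
        Wfull = np.concatenate((W, [0.0]))
        own = data.event[test_idx] * (eta_i - np.log(w_i + Wfull[pos]))
        out[test_idx] = own - cum_term
    if not np.all(seen):
        raise ValueError("folds must cover all subjects")
    return out


def cvpl_verweij(data: SurvivalData, folds=None, **kwargs) -> float:
    """Total cross-validated partial log-likelihood (LOO if ``folds=None``)."""
    return float(cvpl_contributions(data, folds, **kwargs).sum())


def write_coefficients_csv(fit: CoxPH, path, names=None,
                           delimiter: str = ",") -> None:
    """Write the fitted coefficient table as ``name,estimate`` rows."""
    import pandas as pd

    if names is None:
        names = [f"x{j + 1}" for j in range(fit.coef_.size)]
    pd.DataFrame({"name": list(names), "estimate": fit.coef_}).to_csv(
        path, sep=delimiter, index=False)
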