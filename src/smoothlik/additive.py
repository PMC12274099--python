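"""Aalen additive hazards model, with optional ridge penalization.

The hazard is additive in the covariates with time-varying coefficients,

    h(t | x) = beta_0(t) + beta_1(t) x_1 + ... + beta_p(t) x_p,

estimated through the cumulative regression functions B_j(t) = int_0^t
beta_j(s) ds.  At each event time t the increment is the least-squares
solution on the at-risk design X(t) (row i equals Y_i(t) * (1, x_i')):

    dB(t) = (X(t)'X(t))^(-1) X(t)' dN(t)            (OLS, Aalen)
    dB(t) = (X(t)'X(t) + lambda I)^(-1) X(t)' dN(t) (ridge)

with dB(t) = 0 whenever X(t) is rank deficient (the same rule is kept under
ridge).  Predicted cumulative hazards H(t|x) = x*' B(t) may decrease in t --
a well-known defect of the OLS estimator that ridge mitigates but does not
remove; negative increments are preserved and only the log of the smoothed
hazard is floored downstream.

Ridge is applied on the raw design (no covariate standardization), and by
default penalizes all columns including the intercept; ``penalize_intercept=
False`` restricts the penalty to the covariate coefficient processes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .core import StepFunction, SurvivalData, as_survival_arrays
from .cox import CoxPH

__all__ = ["AalenAdditive", "fit_additive", "predict_cumhaz_additive"]


class AalenAdditive(BaseEstimator):
    """Aalen additive hazards estimator with ridge-penalized increments.

    Parameters
    ----------
    ridge_lambda : float
        Penalty lambda >= 0; 0 gives Aalen's OLS estimator.
    penalize_intercept : bool
        Whether the intercept column is included in the ridge penalty.
    rank_tol : float
        X(t) is declared rank deficient when its smallest singular value is
        below ``rank_tol`` times its largest; the increment is then zero.

    Attributes
    ----------
    cumulative_coefs_ : list of StepFunction
        One cumulative regression function B_j(t) per design column
        (intercept first), with jumps at the unique training event times.
    design_names_ : list of str
        Column names, ``["intercept", ...covariates]``.
    event_times_ : ndarray
        Sorted unique training event times.
    """

    def __init__(self, ridge_lambda: float = 0.0, penalize_intercept: bool = True,
                 rank_tol: float = 1e-10):
        self.ridge_lambda = ridge_lambda
        self.penalize_intercept = penalize_intercept
        self.rank_tol = rank_tol

    def fit(self, X, y, feature_names=None):
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        time, event = as_survival_arrays(y)
        X = CoxPH._check_X(X, n=time.size)
        n, p = X.shape
        design = np.column_stack([np.ones(n), X])
        q = p + 1
        pen = np.eye(q) * self.ridge_lambda
        if not self.penalize_intercept:
            pen[0, 0] = 0.0
        order = np.argsort(time, kind="stable")
        t_s, e_s, D_s = time[order], event[order], design[order]
        uniq = np.unique(t_s[e_s == 1])
        if uniq.size == 0:
            raise ValueError("data contains no events")
        dB = np.zeros((uniq.size, q))
        start = np.searchsorted(t_s, uniq, side="left")  # first at-risk row
        for k, (t_k, s_k) in enumerate(zip(uniq, start)):
            Xt = D_s[s_k:]                                # at-risk rows only
            sv = np.linalg.svd(Xt, compute_uv=False)
            if sv.size < q or sv[-1] < self.rank_tol * sv[0]:
                continue                                  # dB(t) = 0
            at_t = slice(s_k, np.searchsorted(t_s, t_k, side="right"))
            xdn = D_s[at_t][e_s[at_t] == 1].sum(axis=0)   # X(t)' dN(t)
            dB[k] = np.linalg.solve(Xt.T @ Xt + pen, xdn)
        self.event_times_ = uniq
        self.design_names_ = ["intercept"] + (
            list(feature_names) if feature_names is not None
            else [f"x{j + 1}" for j in range(p)])
        self.cumulative_coefs_ = [StepFunction(uniq, dB[:, j]) for j in range(q)]
        self._dB = dB
        self.n_features_in_ = p
        return self

    def _validate_for_predict(self, X):
        if not hasattr(self, "cumulative_coefs_"):
            raise ValueError("estimator is not fitted")
        return CoxPH._check_X(X, p=self.n_features_in_)

    def predict_cumulative_hazard(self, X):
        """Per-subject ``H(t|x) = x*' B(t)`` step functions.

        Increments may be negative; consumers that need a hazard guard the
        log with their floor.
        """
        X = self._validate_for_predict(X)
        design = np.column_stack([np.ones(X.shape[0]), X])
        incr = design @ self._dB.T                        # (n_test, n_times)
        return [StepFunction(self.event_times_, row) for row in incr]

    def cumulative_hazard_at(self, X, t, side: str = "right") -> np.ndarray:
        """Paired evaluation ``H(t_i | x_i)``."""
        X = self._validate_for_predict(X)
        design = np.column_stack([np.ones(X.shape[0]), X])
        cum = np.vstack([np.zeros(design.shape[1]),
                         np.cumsum(self._dB, axis=0)])
        idx = np.searchsorted(self.event_times_, np.asarray(t, float), side=side)
        return np.einsum("ij,ij->i", design, cum[idx])

    def survival_at(self, X, t, side: str = "right") -> np.ndarray:
        return np.exp(-self.cumulative_hazard_at(X, t, side=side))


def fit_additive(data: SurvivalData, ridge_lambda: float = 0.0,
                 **kwargs) -> AalenAdditive:
    """Fit an :class:`AalenAdditive` on a :class:`SurvivalData` sample."""
    est = AalenAdditive(ridge_lambda=ridge_lambda, **kwargs)
    return est.fit(data.X, data.y, feature_names=data.covariate_names)


def predict_cumhaz_additive(fit: AalenAdditive, x) -> StepFunction:
    """Predicted cumulative-hazard step function for one covariate vector."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return fit.predict_cumulative_hazard(x[None, :])[0]


def write_cumulative_coefs_csv(fit: AalenAdditive, path,
                               delimiter: str = ",") -> None:
    """Write the cumulative regression functions B_j(t) as one CSV.

    Columns: ``time`` plus one cumulative-coefficient column per design
    column (intercept first) -- the layout used to plot the estimated
    time-varying effects.
    """
    import pandas as pd

    frame = pd.DataFrame({"time": fit.event_times_})
    for name, sf in zip(fit.design_names_, fit.cumulative_coefs_):
        frame[name] = sf.cumulative
    frame.to_csv(path, sep=delimiter, index=False)
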