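"""Core containers for right-censored survival data and step-function algebra.

Everything downstream works on two objects:

* :class:`SurvivalData` -- right-censored observations ``(T_i, delta_i, x_i)``
  with strictly positive follow-up times and a 0/1 event indicator.
* :class:`StepFunction` -- a right-continuous piecewise-constant function with
  jumps at a finite set of times.  Cumulative hazards, survival curves and the
  Kaplan--Meier censoring-distribution estimate are all represented this way.

Semiparametric survival estimators produce cumulative hazards that jump only
at event times seen in the training data, so step functions are the universal
currency between the fitters, the kernel smoother and the loss functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "StepFunction",
    "SurvivalData",
    "risk_set",
    "km_censoring",
    "warp_time",
    "read_survival_csv",
    "write_step_function_csv",
]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function ``f(t) = initial + sum_{t_j <= t} dj``.

    Parameters
    ----------
    times : array-like
        Strictly increasing, strictly positive jump locations.
    increments : array-like
        Jump sizes, one per jump location.  May be negative (e.g. survival
        curves stored with ``initial=1``, or additive-hazards predictions).
    initial : float
        Value on ``[0, times[0])``.  Defaults to 0 (cumulative hazards);
        survival-type functions use 1.
    """

    times: np.ndarray
    increments: np.ndarray
    initial: float = 0.0
    _cumulative: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        incr = np.asarray(self.increments, dtype=float)
        if times.ndim != 1 or incr.ndim != 1 or times.shape != incr.shape:
            raise ValueError("times and increments must be 1-d of equal length")
        if times.size and (not np.all(np.isfinite(times)) or times[0] <= 0.0):
            raise ValueError("jump times must be finite and strictly positive")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("jump times must be strictly increasing")
        if not np.all(np.isfinite(incr)):
            raise ValueError("increments must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "increments", incr)
        object.__setattr__(self, "_cumulative", self.initial + np.cumsum(incr))

    @property
    def cumulative(self) -> np.ndarray:
        """Function value at each jump time (right limit)."""
        return self._cumulative

    def __call__(self, t, side: str = "right"):
        """Evaluate at ``t`` (scalar or array).

        ``side='right'`` gives the right-continuous value (a jump counts at
        its own time); ``side='left'`` gives the left limit ``f(t-)``.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("step functions are defined on t >= 0 only")
        idx = np.searchsorted(self.times, t_arr, side=side)
        vals = np.concatenate(([self.initial], self._cumulative))[idx]
        return vals if t_arr.ndim else float(vals)

    def evaluate_left(self, t):
        """Left limit ``f(t-)``."""
        return self(t, side="left")

    @property
    def final_value(self) -> float:
        return float(self._cumulative[-1]) if self.times.size else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "increment": self.increments,
             "cumulative": self._cumulative}
        )


def evaluate_step(f: StepFunction, t):
    """Functional alias for ``f(t)`` (right-continuous evaluation)."""
    return f(t)


class SurvivalData:
    """Right-censored survival sample ``(T_i, delta_i, x_i), i = 1..n``.

    ``time`` holds the observed follow-up times ``T_i = min(Ttilde_i, C_i)``
    (strictly positive), ``event`` the indicators ``delta_i`` (1 = event,
    0 = censored) and ``covariates`` an ``(n, p)`` matrix with named columns
    (``p`` may be 0).  Tied times are allowed in storage; fitters resolve
    event-time ties by the Breslow convention and treat events as preceding
    censorings at the same time.
    """

    def __init__(self, time, event, covariates=None, covariate_names=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1:
            raise ValueError("time must be 1-d")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all times must be strictly positive and finite")
        if event.shape != time.shape:
            raise ValueError("event and time must have equal length")
        ev = event.astype(float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("event values must be 0 or 1")
        if covariates is None:
            covariates = np.empty((time.size, 0))
        if isinstance(covariates, pd.DataFrame):
            if covariate_names is None:
                covariate_names = [str(c) for c in covariates.columns]
            covariates = covariates.to_numpy(dtype=float)
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != time.size:
            raise ValueError("covariate row count must equal number of subjects")
        if not np.all(np.isfinite(covariates)):
            raise ValueError("covariates must be finite")
        if covariate_names is None:
            covariate_names = [f"x{j + 1}" for j in range(covariates.shape[1])]
        if len(covariate_names) != covariates.shape[1]:
            raise ValueError("covariate_names length mismatch")
        self.time = time
        self.event = ev.astype(np.int64)
        self.covariates = covariates
        self.covariate_names = list(covariate_names)

    # -- basic facts -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def event_times(self) -> np.ndarray:
        """Sorted observed event times (may contain ties)."""
        return np.sort(self.time[self.event == 1])

    def has_tied_event_times(self) -> bool:
        """The fitters assume unique event times; ties are a reportable
        condition (resolved by the Breslow convention), never silent."""
        et = self.event_times
        return bool(et.size > 1 and np.any(np.diff(et) == 0))

    # -- conversions -------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.covariates

    @property
    def y(self) -> np.ndarray:
        """Structured outcome array with fields ``event`` (bool), ``time``."""
        out = np.empty(self.n, dtype=[("event", "?"), ("time", "<f8")])
        out["event"] = self.event.astype(bool)
        out["time"] = self.time
        return out

    def subset(self, idx) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(self.time[idx], self.event[idx],
                            self.covariates[idx], self.covariate_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalData":
        if "time" not in df.columns or "event" not in df.columns:
            raise ValueError("data frame must contain 'time' and 'event' columns")
        cov_cols = [c for c in df.columns if c not in ("time", "event")]
        return cls(df["time"].to_numpy(float), df["event"].to_numpy(),
                   df[cov_cols].to_numpy(float) if cov_cols else None,
                   cov_cols or None)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SurvivalData(n={self.n}, events={self.n_events}, "
                f"covariates={self.covariate_names})")


def as_survival_arrays(y):
    """Normalize an outcome ``y`` into ``(time, event)`` float/int arrays.

    Accepts a structured array with ``event``/``time`` fields (the
    scikit-survival convention), a ``(time, event)`` tuple/list, an ``(n, 2)``
    array with columns ``time, event``, or a :class:`SurvivalData`.
    """
    if isinstance(y, SurvivalData):
        return y.time, y.event
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        if not {"time", "event"} <= names:
            raise ValueError("structured outcome must have 'event' and 'time' fields")
        return y["time"].astype(float), y["event"].astype(np.int64)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        time = np.asarray(y[0], dtype=float)
        event = np.asarray(y[1])
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("outcome must be structured, (time, event) or (n, 2)")
        time, event = arr[:, 0], arr[:, 1]
    data = SurvivalData(time, event)  # reuse validation
    return data.time, data.event


def risk_set(time: np.ndarray, t: float) -> np.ndarray:
    """Indices of subjects still at risk at ``t``: ``R(t) = {j : T_j >= t}``."""
    return np.flatnonzero(np.asarray(time, dtype=float) >= t)


def km_censoring(data: SurvivalData) -> StepFunction:
    """Kaplan--Meier estimate of the censoring survival function ``Ghat``.

    This is the product-limit estimator applied with the event indicator
    flipped (censorings are the "events"), used as the inverse-probability-
    of-censoring weight in Brier-type scores.  Returned as a
    :class:`StepFunction` with ``initial=1`` and non-positive increments, so
    ``Ghat(t)`` and the left limit ``Ghat(t-)`` are queryable at any ``t``;
    queries beyond the last observed time return the last value.
    """
    if data.n == 0:
        raise ValueError("empty data")
    return _km(data.time, 1 - data.event)


def km_survival(data: SurvivalData) -> StepFunction:
    """Ordinary Kaplan--Meier estimate of the event-time survival function."""
    if data.n == 0:
        raise ValueError("empty data")
    return _km(data.time, data.event)


def _km(time: np.ndarray, died: np.ndarray) -> StepFunction:
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    d_sorted = np.asarray(died)[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    n = time.size
    at_risk = n - start
    deaths = np.add.reduceat(d_sorted, start)
    keep = deaths > 0
    if not np.any(keep):
        return StepFunction(np.empty(0), np.empty(0), initial=1.0)
    factors = 1.0 - deaths[keep] / at_risk[keep]
    surv = np.cumprod(factors)
    increments = np.diff(np.concatenate(([1.0], surv)))
    return StepFunction(uniq[keep], increments, initial=1.0)


def warp_time(data: SurvivalData, g: Callable[[np.ndarray], np.ndarray]) -> SurvivalData:
    """Apply a strictly increasing time warp ``g`` to the follow-up times.

    Semiparametric fits depend on the data only through event-time ranks, so
    results must be unchanged (on the rank scale) under any such warp; this
    helper exists to exercise that invariance.  Non-monotonicity of ``g`` on
    the observed times is detected and rejected.
    """
    new_time = np.asarray(g(data.time), dtype=float)
    order = np.argsort(data.time, kind="stable")
    if np.any(np.diff(new_time[order]) < 0) or np.any(new_time <= 0):
        raise ValueError("warp must be strictly increasing and positive")
    # strictness: distinct inputs must stay distinct
    t_sorted = data.time[order]
    w_sorted = new_time[order]
    distinct = np.diff(t_sorted) > 0
    if np.any(distinct & (np.diff(w_sorted) <= 0)):
        raise ValueError("warp must be strictly increasing")
    return SurvivalData(new_time, data.event, data.covariates, data.covariate_names)


def read_survival_csv(path, delimiter: str = ",") -> SurvivalData:
    """Read ``time,event,<covariates...>`` delimited text (header required)."""
    df = pd.read_csv(path, sep=delimiter)
    return SurvivalData.from_frame(df)


def write_survival_csv(data: SurvivalData, path, delimiter: str = ",") -> None:
    data.to_frame().to_csv(path, sep=delimiter, index=False)


def write_step_function_csv(f: StepFunction, path, delimiter: str = ",") -> None:
    """Write a step function as ``time,increment,cumulative`` rows."""
    f.to_frame().to_csv(path, sep=delimiter, index=False)
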