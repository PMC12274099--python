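"""Nearest-neighbor kernel smoothing of step cumulative hazards.

A step-function survival estimate assigns zero hazard to any time not seen in
the training data, so the predictive log-likelihood

    L(S(.|x), t, delta) = delta * log h(t|x) - H(t|x)

of a test subject whose event time is new is minus infinity regardless of the
model.  The fix implemented here estimates the hazard by smoothing the
cumulative hazard with a uniform kernel whose bandwidth adapts to the local
density of training event times: the window around a query time t reaches to
the m-th training event time on each side (default m=5), so it always holds
2m neighbors (fewer near the boundaries).

With a uniform kernel the smoothed hazard is simply

    h_s(t|x) = (mass of dH(.|x) inside the window) / (window length).

Window endpoints sit AT the m-th neighbors, so the set of jumps inside the
window is determined by event-time ranks alone.  As a consequence the
difference in total smoothed predictive log-likelihood between two models
trained on the same data is exactly invariant under any strictly increasing
warp of the time axis -- the property that makes rank-based semiparametric
estimates attractive in the first place.  Boundary rules: below the first
event time the window is truncated at 0; beyond the last event time a
one-sided window over the 2m nearest event times below t is used, extended
symmetrically above t.

For a Cox model the smoothed hazard factorizes, h_s(t|x) = e^{x'beta} *
h0_s(t), so only the Breslow baseline needs smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StepFunction

__all__ = [
    "SmootherConfig",
    "nn_window",
    "smooth_hazard",
    "smoothed_loglik",
    "smoothed_baseline",
]


@dataclass(frozen=True)
class SmootherConfig:
    """Settings of the nearest-neighbor uniform-kernel smoother.

    ``m`` is the number of training event times the window reaches on each
    side of the query time (default 5, a practical small-sample choice);
    ``hazard_floor`` guards the log of a zero or negative smoothed hazard so
    the loss is always finite.  Only the uniform kernel on [-1, 1] is
    supported.
    """

    m: int = 5
    kernel: str = "uniform"
    hazard_floor: float = 1e-12

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.kernel != "uniform":
            raise ValueError("only the uniform kernel is supported")
        if not self.hazard_floor > 0:
            raise ValueError("hazard_floor must be positive")


def nn_windows(train_event_times: np.ndarray, t, m: int):
    """Vectorized nearest-neighbor windows ``[lo_i, hi_i]`` for query times.

    ``train_event_times`` must be sorted ascending.  Returns two arrays of
    window endpoints.  The window reaches to the m-th event time strictly
    below t and the m-th at/above t (an event time exactly at t counts to the
    upper side); with fewer than m on a side all available ones are used.
    Truncated at 0 when no event time lies below t; beyond the last event
    time the window covers the 2m nearest event times below t and is extended
    symmetrically above t.
    """
    times = np.asarray(train_event_times, dtype=float)
    if times.size == 0:
        raise ValueError("no training event times to smooth over")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("query times must be nonnegative")
    n = times.size
    idx = np.searchsorted(times, t_arr, side="left")   # count strictly below
    lo = np.where(idx > 0, times[np.maximum(idx - m, 0)], 0.0)
    hi_idx = np.minimum(idx + m, n) - 1
    hi = times[hi_idx]
    beyond = idx == n                                   # no event time >= t
    if np.any(beyond):
        lo_b = times[np.maximum(n - 2 * m, 0)]
        lo = np.where(beyond, lo_b, lo)
        hi = np.where(beyond, 2.0 * t_arr - lo_b, hi)
    if np.any(hi <= lo):
        raise ValueError("zero-length smoothing window "
                         "(all training event times identical)")
    return lo, hi


def nn_window(train_event_times, t: float, m: int):
    """Scalar window ``(lo, hi)`` around query time ``t``; see :func:`nn_windows`."""
    lo, hi = nn_windows(train_event_times, float(t), m)
    return float(lo[0]), float(hi[0])


def _window_mass(H: StepFunction, lo, hi):
    """Mass of ``dH`` on the closed window ``[lo, hi]``."""
    return H(hi, side="right") - H(lo, side="left")


def smooth_hazard(H: StepFunction, t: float, cfg: SmootherConfig,
                  train_event_times=None) -> float:
    """Uniform-kernel nearest-neighbor hazard estimate at ``t``.

    ``H`` must jump only at ``train_event_times`` (defaults to the jump times
    of ``H`` itself); the neighbor windows are always formed from the
    training event times so that test subjects of competing models share the
    same windows.
    """
    times = H.times if train_event_times is None else np.asarray(train_event_times, float)
    if train_event_times is not None and H.times.size:
        if not np.all(np.isin(H.times, times)):
            raise ValueError("H has jumps outside the training event times")
    lo, hi = nn_window(times, t, cfg.m)
    return float(_window_mass(H, lo, hi) / (hi - lo))


def smoothed_loglik(Hpred: StepFunction, t: float, delta: int,
                    cfg: SmootherConfig, train_event_times=None) -> float:
    """Smoothed predictive log-likelihood of one test subject.

    ``delta * log(max(h_s(t|x), hazard_floor)) - H(t|x)``; censored subjects
    (delta=0) need no smoothing and contribute exactly ``-H(t|x)``.  The
    result is always finite.
    """
    Ht = float(Hpred(t))
    if not delta:
        return -Ht
    hs = smooth_hazard(Hpred, t, cfg, train_event_times)
    return float(np.log(max(hs, cfg.hazard_floor)) - Ht)


def smoothed_baseline(fit, t: float, cfg: SmootherConfig) -> float:
    """Smoothed Breslow baseline hazard ``h0_s(t)`` of a fitted Cox model.

    For a Cox model the smoothed subject hazard is ``e^{x'beta} * h0_s(t)``,
    so smoothing the baseline suffices.
    """
    return smooth_hazard(fit.baseline_hazard_, t, cfg)
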