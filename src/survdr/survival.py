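"""Nonparametric survival kernel: Kaplan-Meier estimation, the censored
Brier score, its time integral, and the two-group log-rank test.

All estimators are product-limit based.  Ties between events and censorings
at the same time follow the standard convention: events precede censorings,
i.e. subjects censored at t are still at risk for events at t.

The Brier score for censored observations follows Graf et al.'s
inverse-probability-of-censoring weighting: for an evaluation time t, a
subject with an observed event at t_i <= t contributes (0 - pred)^2 / G(t_i-),
a subject still under observation at t (t_i > t) contributes
(1 - pred)^2 / G(t), and a subject censored at or before t contributes 0,
where G is the Kaplan-Meier estimate of the censoring distribution and
G(t-) its left limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SurvivalData

__all__ = [
    "KMCurve",
    "km_estimate",
    "censoring_km",
    "brier_score",
    "integrated_brier",
    "logrank_test",
]


@dataclass
class KMCurve:
    """A right-continuous step survival function on a discrete time grid.

    ``grid`` holds the ordered distinct observed times, ``surv`` the
    product-limit estimate at each grid time, ``at_risk`` the number of
    subjects at risk just before each grid time and ``n_events`` the number
    of events at each grid time.  Before the first grid time the curve
    equals 1.
    """

    grid: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """Value at time(s) t: step value at the largest grid time <= t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.grid, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)
        return out if out.ndim else float(out)

    def evaluate_left(self, t) -> np.ndarray:
        """Left limit at time(s) t: step value at the largest grid time < t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.grid, t, side="left") - 1
        out = np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)
        return out if out.ndim else float(out)


def _check_cohort(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty cohort")
    if not np.all(np.isfinite(times)) or np.any(times < 0):
        raise ValueError("invalid time: times must be finite and >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return times, events.astype(float)


def km_estimate(times, events) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival estimate.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over the distinct observed times
    t_i, with d_i the events at t_i and n_i the subjects at risk (observed
    time >= t_i).  Times with no events contribute a factor of 1 but are
    kept on the grid so that risk-set sizes remain available.
    """
    times, events = _check_cohort(times, events)
    grid, inv = np.unique(times, return_inverse=True)
    n_grid = grid.size
    counts = np.bincount(inv, minlength=n_grid)
    d = np.bincount(inv, weights=events, minlength=n_grid)
    at_risk = times.size - (np.cumsum(counts) - counts)
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(grid=grid, surv=surv, at_risk=at_risk.astype(int), n_events=d.astype(int))


def censoring_km(times, events) -> KMCurve:
    """Kaplan-Meier estimate G of the censoring distribution.

    The product-limit estimator applied to (t_i, 1 - delta_i): censorings
    are treated as the events of interest.
    """
    times, events = _check_cohort(times, events)
    return km_estimate(times, 1.0 - events)


def brier_score(pred_surv, times, events, t: float, G: KMCurve) -> float:
    """Censored Brier score BS(t) for per-subject predictions at time t.

    ``pred_surv`` gives each subject's predicted probability of surviving
    past t.  Weighting follows Graf et al. (see module docstring).  Raises
    if a required censoring weight is zero; subjects are never silently
    dropped.
    """
    times, events = _check_cohort(times, events)
    pred = np.asarray(pred_surv, dtype=float)
    if pred.shape != times.shape:
        raise ValueError("pred_surv must have one value per subject")
    if np.any(pred < 0) or np.any(pred > 1):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    if t <= 0:
        raise ValueError("evaluation time t must be > 0")

    had_event = (times <= t) & (events == 1)
    under_obs = times > t
    total = 0.0
    if had_event.any():
        w = G.evaluate_left(times[had_event])
        if np.any(w <= 0):
            raise ValueError("inestimable censoring weight")
        total += float(np.sum(pred[had_event] ** 2 / w))
    if under_obs.any():
        g_t = G.evaluate(t)
        if g_t <= 0:
            raise ValueError("inestimable censoring weight")
        total += float(np.sum((1.0 - pred[under_obs]) ** 2 / g_t))
    return total / times.size


def integrated_brier(pred_curves, data: SurvivalData, t_max: float | None = None) -> float:
    """Integrated Brier score IBS = (1/t_max) * int_0^t_max BS(t) dt.

    ``pred_curves`` is one predicted :class:`KMCurve` per subject.  BS(t)
    is a right-continuous step function that only changes at observed
    times, so the integral is evaluated exactly by step decomposition.
    ``t_max`` defaults to the largest observed event time.
    """
    times, events = data.time, data.event
    if t_max is None:
        if not (events == 1).any():
            raise ValueError("no events: t_max cannot be defaulted")
        t_max = float(times[events == 1].max())
    if t_max <= 0 or t_max > times.max():
        raise ValueError("t_max must be in (0, max observed time]")
    if len(pred_curves) != data.n_subjects:
        raise ValueError("one predicted curve per subject is required")

    G = censoring_km(times, events)
    interior = np.unique(times)
    interior = interior[(interior > 0) & (interior < t_max)]
    seg_left = np.concatenate(([0.0], interior))
    seg_right = np.concatenate((interior, [t_max]))

    total = 0.0
    for s, length in zip(seg_left, seg_right - seg_left):
        if length <= 0:
            continue
        # BS is constant on [s, next); evaluate with the categorisation at s
        # (for the leading segment any 0 < t < first time gives the same value).
        pred = np.array([c.evaluate(s) for c in pred_curves])
        total += _brier_at(pred, times, events, s, G) * length
    return total / t_max


def _brier_at(pred, times, events, s, G) -> float:
    """BS on the segment starting at s; categorisation uses times <= s."""
    had_event = (times <= s) & (events == 1)
    under_obs = times > s
    total = 0.0
    if had_event.any():
        w = G.evaluate_left(times[had_event])
        if np.any(w <= 0):
            raise ValueError("inestimable censoring weight")
        total += float(np.sum(pred[had_event] ** 2 / w))
    if under_obs.any():
        g = G.evaluate(s)
        if g <= 0:
            raise ValueError("inestimable censoring weight")
        total += float(np.sum((1.0 - pred[under_obs]) ** 2 / g))
    return total / times.size


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test.

    Returns ``(chi_square, p_value, df)`` with df = 1.  The statistic is the
    usual (O - E)^2 / V form summed over the distinct event times of the
    pooled sample, with the hypergeometric variance.
    """
    ta, ea = _check_cohort(times_a, events_a)
    tb, eb = _check_cohort(times_b, events_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("degenerate grouping")

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])

    grid, inv = np.unique(times, return_inverse=True)
    m = grid.size
    d_all = np.bincount(inv, weights=events, minlength=m)
    d_a = np.bincount(inv, weights=events * (group == 0), minlength=m)
    c_all = np.bincount(inv, minlength=m)
    c_a = np.bincount(inv, weights=(group == 0).astype(float), minlength=m)
    n_all = times.size - (np.cumsum(c_all) - c_all)
    n_a = ta.size - (np.cumsum(c_a) - c_a)

    mask = d_all > 0
    observed = d_a[mask].sum()
    expected = np.sum(d_all[mask] * n_a[mask] / n_all[mask])
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_all[mask] > 1,
            d_all[mask]
            * (n_a[mask] / n_all[mask])
            * (1 - n_a[mask] / n_all[mask])
            * (n_all[mask] - d_all[mask])
            / (n_all[mask] - 1),
            0.0,
        )
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0, 1
    chi2 = (observed - expected) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, 1
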