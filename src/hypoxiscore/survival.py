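"""Kaplan-Meier relapse-free survival and the Mantel-Haenszel (log-rank) test.

The product-limit estimator and the two-group log-rank statistic are written
directly on risk tables so that the observed/expected decomposition is
available (the O/E hazard-ratio summary needs it) and so that the statistic
can be evaluated for many candidate dichotomies of the same cohort at once
(:func:`logrank_profile`), which is what the risk-score cut-point search
iterates over.

Ties follow the standard product-limit convention: at equal times, events
are processed before censorings (a subject censored at t is still at risk
for an event at t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "SurvivalPoint",
    "LogRankResult",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "logrank_profile",
]


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier step estimate.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``.  S(0) = 1 by construction.
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n_subjects: int = 0
    total_events: int = 0

    @property
    def max_observed_time(self) -> float:
        all_t = np.concatenate([self.times, self.censor_times])
        return float(all_t.max()) if all_t.size else 0.0


@dataclass(frozen=True)
class SurvivalPoint:
    """S(t) and its complement at one time point."""

    time: float
    survival: float
    cumulative_incidence: float
    extrapolated: bool


@dataclass
class LogRankResult:
    """Two-group Mantel-Haenszel test summary.

    ``observed``/``expected`` are per group (index 0 = first label in
    ``group_labels``); ``hazard_ratio`` is the O/E summary
    (O_1/E_1)/(O_0/E_0), ``inf`` when the reference group has expected
    events but none observed.
    """

    group_labels: tuple
    observed: np.ndarray
    expected: np.ndarray
    variance: float
    statistic: float
    p_value: float
    df: int = 1
    hazard_ratio: float = np.nan
    hazard_ratio_degenerate: bool = False


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times <= 0):
        raise ValueError("all times must be > 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimate of the survival function.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with censored subjects leaving the risk set just after their time.
    """
    times, events = _check_times_events(times, events)
    event_times = np.unique(times[events == 1])
    n_at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    n_events = np.array(
        [((times == t) & (events == 1)).sum() for t in event_times], dtype=int
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_events / n_at_risk
    survival = np.cumprod(factors) if event_times.size else np.array([])
    return SurvivalCurve(
        times=event_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        survival=survival,
        censor_times=np.sort(times[events == 0]),
        n_subjects=int(times.size),
        total_events=int(events.sum()),
    )


def survival_at(curve: SurvivalCurve, t: float) -> SurvivalPoint:
    """Right-continuous lookup of S(t), with the cumulative incidence 1 - S(t).

    Beyond the last observed time the last value is carried forward and the
    result is flagged as extrapolated.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right")
    s = 1.0 if idx == 0 else float(curve.survival[idx - 1])
    extrapolated = t > curve.max_observed_time
    return SurvivalPoint(
        time=float(t),
        survival=s,
        cumulative_incidence=1.0 - s,
        extrapolated=extrapolated,
    )


def _risk_tables(times: np.ndarray, events: np.ndarray):
    """Shared per-event-time totals: distinct event times, n_k, d_k and the
    per-subject at-risk / event incidence matrices used for vectorization."""
    event_times = np.unique(times[events == 1])
    at_risk = times[:, None] >= event_times[None, :]  # n x K
    event_here = (times[:, None] == event_times[None, :]) & (events == 1)[:, None]
    n_k = at_risk.sum(axis=0)
    d_k = event_here.sum(axis=0)
    return event_times, at_risk, event_here, n_k, d_k


def logrank_profile(times, events, membership: np.ndarray):
    """Log-rank statistic for many dichotomies of one cohort at once.

    ``membership`` is an (m, n) boolean array; row j defines group 1 of the
    j-th dichotomy.  Returns ``(statistics, observed1, expected1, variances)``
    each of length m.  A dichotomy with zero variance (no events, or one
    group empty at every event time) gets statistic ``nan``.
    """
    times, events = _check_times_events(times, events)
    membership = np.atleast_2d(np.asarray(membership, dtype=bool))
    if membership.shape[1] != times.size:
        raise ValueError("membership row length must match number of subjects")
    _, at_risk, event_here, n_k, d_k = _risk_tables(times, events)
    if d_k.size == 0:
        raise ValueError("no events: log-rank statistic undefined")
    n1 = membership.astype(float) @ at_risk.astype(float)  # m x K
    o1 = membership.astype(float) @ event_here.astype(float)
    frac = n1 / n_k
    e1 = (d_k * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_factor = np.where(n_k > 1, (n_k - d_k) / (n_k - 1.0), 0.0)
    v = (d_k * frac * (1.0 - frac) * var_factor).sum(axis=1)
    obs1 = o1.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(v > 0, (obs1 - e1) ** 2 / v, np.nan)
    return stat, obs1, e1, v


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group Mantel-Haenszel test on right-censored times.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; the summed
    differences are referred to chi-square on 1 df.
    """
    times, events = _check_times_events(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"exactly 2 groups required, got {labels.size}")
    if events.sum() == 0:
        raise ValueError("no events: log-rank statistic undefined")
    member1 = groups == labels[1]
    stat, o1, e1, v = logrank_profile(times, events, member1[None, :])
    stat, o1, e1, v = float(stat[0]), float(o1[0]), float(e1[0]), float(v[0])
    total_events = float(events.sum())
    o = np.array([total_events - o1, o1])
    e = np.array([total_events - e1, e1])
    if v <= 0:
        raise ValueError("zero log-rank variance: groups do not overlap in risk sets")
    p = float(stats.chi2.sf(stat, df=1))
    degenerate = (o[0] == 0 and e[0] > 0) or (o[1] == 0 and e[1] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = o / e
        hr = float(rates[1] / rates[0]) if rates[0] > 0 else float("inf")
    return LogRankResult(
        group_labels=tuple(labels),
        observed=o,
        expected=e,
        variance=v,
        statistic=stat,
        p_value=p,
        hazard_ratio=hr,
        hazard_ratio_degenerate=bool(degenerate),
    )
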