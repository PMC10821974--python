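"""Product-limit survival estimation and the two-group log-rank test.

Implemented directly from the defining formulas. The Kaplan-Meier estimate
at event time t_j is the product over event times t_i <= t_j of
(1 - d_i / n_i), where d_i counts deaths at t_i and n_i the subjects still
at risk; censored subjects leave the risk set after their censoring time,
and when an event and a censoring share a timestamp the event is counted
first (the censored subject is still at risk). The log-rank statistic
compares observed and expected events per group under the hypergeometric
model at each distinct event time, with the usual variance sum and a
chi-square reference distribution on 1 degree of freedom; no continuity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TaxonTable


@dataclass
class KMCurve:
    """Kaplan-Meier estimate evaluated at the distinct event times."""

    event_times: np.ndarray   # strictly increasing
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray      # non-increasing product-limit estimate
    censor_times: np.ndarray  # timestamps of censored subjects

    def survival_at(self, t: float) -> float:
        """S(t): the estimate just after the last event time <= t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    observed: np.ndarray  # events per group (A, B)
    expected: np.ndarray
    chi_square: float
    p_value: float


def _check_times(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival data")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate with right censoring."""
    times, events = _check_times(times, events)
    event_times = np.unique(times[events == 1])
    n_at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    for j, t in enumerate(event_times):
        n_at_risk[j] = int((times >= t).sum())
        n_events[j] = int(((times == t) & (events == 1)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(event_times, n_at_risk, n_events, survival,
                   np.sort(times[events == 0]))


def logrank_test(group_a: tuple, group_b: tuple) -> LogRankResult:
    """Unweighted two-group log-rank test.

    Each group is a ``(times, events)`` pair. At every distinct pooled event
    time the expected number of group-A events is d * nA / n under the
    hypergeometric model, with variance d (nA/n)(nB/n)(n - d)/(n - 1); the
    statistic is (O_A - E_A)^2 / V with a chi-square(1) p-value.
    """
    ta, ea = _check_times(*group_a)
    tb, eb = _check_times(*group_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.r_[np.ones(len(ta), bool), np.zeros(len(tb), bool)]
    if events.sum() == 0:
        raise ValueError("log-rank undefined without events")
    o_a = e_a = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * ((n - n_a) / n) * (n - d) / (n - 1)
    observed = np.array([o_a, float(events.sum()) - o_a])
    expected = np.array([e_a, float(events.sum()) - e_a])
    if var <= 0:
        return LogRankResult(observed, expected, 0.0, 1.0)
    chi2 = (o_a - e_a) ** 2 / var
    return LogRankResult(observed, expected, float(chi2),
                         float(stats.chi2.sf(chi2, df=1)))


def dichotomize_and_compare(
    table: TaxonTable,
    meta: pd.DataFrame,
    taxon: str,
    cutoff_pct: float,
    subgroup: str | None = None,
) -> tuple[KMCurve, KMCurve, LogRankResult]:
    """Split the cohort at a taxon abundance cutoff and compare survival.

    Samples with the taxon's percent abundance strictly above ``cutoff_pct``
    form the "high" stratum (boundary values go low). ``subgroup`` may
    restrict the analysis to the recurrence or non_recurrence group first.
    Returns ``(km_high, km_low, logrank)``.
    """
    if taxon not in table.values.columns:
        raise KeyError(f"taxon {taxon!r} not in table")
    meta = meta.loc[table.sample_ids]
    abundance = table.values[taxon]
    if subgroup is not None:
        keep = meta["group"] == subgroup
        if not keep.any():
            raise ValueError(f"no samples in subgroup {subgroup!r}")
        meta = meta.loc[keep]
        abundance = abundance.loc[keep]
    high = abundance > cutoff_pct
    if not high.any():
        raise ValueError("high stratum empty")
    if high.all():
        raise ValueError("low stratum empty")
    t = meta["survival_months"].to_numpy(dtype=float)
    e = meta["event"].to_numpy(dtype=int)
    km_high = km_estimate(t[high.to_numpy()], e[high.to_numpy()])
    km_low = km_estimate(t[~high.to_numpy()], e[~high.to_numpy()])
    lr = logrank_test((t[high.to_numpy()], e[high.to_numpy()]),
                      (t[~high.to_numpy()], e[~high.to_numpy()]))
    return km_high, km_low, lr
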