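"""Kaplan-Meier estimation, log-rank comparison and Mantel-Haenszel HR.

Survival records are DataFrames with columns ``time`` (follow-up,
consistent units, never converted) and ``event`` (1 = event observed,
0 = right-censored), optionally ``sample`` and ``group``. The log-rank
machinery exposes the per-group observed and expected event counts and
the hypergeometric variance, from which the Mantel-Haenszel hazard
ratio HR = (O1/E1)/(O2/E2) follows; this estimator inverts exactly
under group swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def as_records(time, event, sample=None, group=None) -> pd.DataFrame:
    """Build a survival record table from columns."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    df = pd.DataFrame({"time": time, "event": event})
    if sample is not None:
        df.insert(0, "sample", list(sample))
    if group is not None:
        df["group"] = list(group)
    return df


def _check(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("need at least one record")
    if (records["time"].to_numpy() < 0).any():
        raise ValueError("negative survival time")
    return records


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray       # ordered distinct event times
    at_risk: np.ndarray     # n_i just before each event time
    events: np.ndarray      # d_i events at each time
    survival: np.ndarray    # S(t_i) = prod_{j<=i} (1 - d_j/n_j)

    def at(self, t: float) -> float:
        """S(t), right-continuous step function with S(0-) = 1."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored times reduce the risk set without producing steps.
    """
    records = _check(records)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    event_times = np.unique(time[event == 1])
    at_risk, d, surv = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int((time >= t).sum())
        d_i = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d.append(d_i)
        surv.append(s)
    return KMCurve(times=event_times, at_risk=np.array(at_risk, dtype=int),
                   events=np.array(d, dtype=int), survival=np.array(surv, dtype=float))


@dataclass
class LogrankResult:
    """Log-rank test with per-group observed/expected tables."""

    chi2: float
    p: float
    observed: np.ndarray     # O_g per group
    expected: np.ndarray     # E_g per group
    variance: np.ndarray     # k x k hypergeometric covariance of O - E
    groups: list             # group labels in table order


def logrank_test(groups) -> LogrankResult:
    """Standard log-rank test across two or more record tables.

    At each distinct event time the risk sets are pooled; per group,
    E_g = d * n_g / n and the covariance of O - E is hypergeometric.
    For two groups the statistic is (O1 - E1)^2 / V11; for k groups,
    the quadratic form on the first k - 1 components.
    """
    groups = [_check(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    times = [g["time"].to_numpy(dtype=float) for g in groups]
    events = [g["event"].to_numpy(dtype=int) for g in groups]
    all_event_times = np.unique(np.concatenate(
        [t[e == 1] for t, e in zip(times, events)]))
    if len(all_event_times) == 0:
        raise ValueError("no events in any group")

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in all_event_times:
        n_g = np.array([(ti >= t).sum() for ti in times], dtype=float)
        d_g = np.array([((ti == t) & (ei == 1)).sum()
                        for ti, ei in zip(times, events)], dtype=float)
        n = n_g.sum()
        d = d_g.sum()
        O += d_g
        E += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    V[a, b] += factor * ((1.0 if a == b else 0.0) * n_g[a] / n
                                         - n_g[a] * n_g[b] / n ** 2)

    if k == 2:
        chi2 = (O[0] - E[0]) ** 2 / V[0, 0] if V[0, 0] > 0 else 0.0
    else:
        diff = (O - E)[: k - 1]
        Vsub = V[: k - 1, : k - 1]
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogrankResult(chi2=float(chi2), p=p, observed=O, expected=E,
                         variance=V, groups=list(range(k)))


@dataclass
class HazardRatioResult:
    """Mantel-Haenszel hazard ratio of group A relative to group B."""

    hr: float
    ci_low: float
    ci_high: float
    logrank: LogrankResult
    unbounded: bool = False


def hazard_ratio(group_a: pd.DataFrame, group_b: pd.DataFrame,
                 alpha: float = 0.05) -> HazardRatioResult:
    """HR = (O_A / E_A) / (O_B / E_B) with a log-scale CI.

    A group with zero expected or observed events makes the ratio
    unbounded; it is reported as inf (or 0) with the flag set rather
    than raising.
    """
    lr = logrank_test([group_a, group_b])
    O, E = lr.observed, lr.expected
    if E[0] == 0 or E[1] == 0 or O[0] == 0 or O[1] == 0:
        hr = np.inf if (E[1] == 0 or O[1] == 0) else 0.0
        return HazardRatioResult(hr=float(hr), ci_low=0.0, ci_high=np.inf,
                                 logrank=lr, unbounded=True)
    hr = (O[0] / E[0]) / (O[1] / E[1])
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1.0 / E[0] + 1.0 / E[1])
    return HazardRatioResult(
        hr=float(hr),
        ci_low=float(hr * np.exp(-z * se)),
        ci_high=float(hr * np.exp(z * se)),
        logrank=lr,
    )


def km_by_group(records: pd.DataFrame) -> dict:
    """KM curve per level of the ``group`` column."""
    if "group" not in records.columns:
        raise ValueError("records need a 'group' column")
    return {g: km_estimate(sub) for g, sub in records.groupby("group", sort=True)}
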