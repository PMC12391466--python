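"""Kaplan-Meier estimation and log-rank (Mantel-Cox) testing with
expression-based stratification.

A survival table holds one row per subject: follow-up time (days),
event indicator (1 = death observed, 0 = censored) and the expression
value of the stratifying gene. Subjects are split into low/high
expression groups (default: median split, ties to high) and the two
survival curves compared by the log-rank test, accumulating the
hypergeometric expectation and variance of group-1 events at each
distinct event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in table.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    if (table["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not set(np.unique(table["event"])) <= {0, 1}:
        raise ValueError("event must be 0/1")
    return table


def km_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the number at risk,
    events, and S(t); S(0) = 1 and S is nonincreasing. Censored times
    reduce the risk set but add no step.
    """
    table = _validate_table(table)
    if len(table) == 0:
        raise ValueError("survival table is empty")
    times = table["time"].values.astype(float)
    events = table["event"].values.astype(int)
    event_times = np.unique(times[events == 1])
    rows = [{"time": 0.0, "at_risk": len(table), "events": 0, "survival": 1.0}]
    s = 1.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d, "survival": s})
    return pd.DataFrame(rows)


@dataclass
class LogRankResult:
    observed: np.ndarray  # events per group (2,)
    expected: np.ndarray  # expected events per group (2,)
    variance: float
    chi2: float
    p: float


def logrank_test(table: pd.DataFrame, groups: np.ndarray) -> LogRankResult:
    """Two-group log-rank (Mantel-Cox) test.

    At each distinct event time with n at risk (n1 in group 1) and d
    events, group-1 events have hypergeometric expectation d·n1/n and
    variance d·(n1/n)·(1−n1/n)·(n−d)/(n−1); χ² = (O1−E1)²/ΣV with a
    1-df chi-square tail. No events at all yields p = 1.
    """
    table = _validate_table(table)
    groups = np.asarray(groups).astype(int)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be binary labels")
    if len(groups) != len(table):
        raise ValueError("groups length mismatch")
    if groups.sum() in (0, len(groups)):
        raise ValueError("both groups must be non-empty")
    times = table["time"].values.astype(float)
    events = table["event"].values.astype(int)
    o = np.array(
        [((events == 1) & (groups == g)).sum() for g in (0, 1)], dtype=float
    )
    e = np.zeros(2)
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        e[0] += d * n1 / n
        e[1] += d * (n - n1) / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return LogRankResult(o, e, 0.0, 0.0, 1.0)
    chi2 = (o[0] - e[0]) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(o, e, float(v), float(chi2), p)


def stratify_by_expression(
    table: pd.DataFrame, rule: str = "median", quantile: float = 0.5
) -> np.ndarray:
    """Binary labels: 1 = low expression (strictly below the split),
    0 = high (ties on the split value go to high)."""
    if "expression" not in table.columns:
        raise ValueError("survival table lacks an expression column")
    values = table["expression"].values.astype(float)
    if np.ptp(values) == 0:
        raise ValueError("all expression values identical; cannot stratify")
    if rule == "median":
        split = float(np.median(values))
    elif rule == "quantile":
        split = float(np.quantile(values, quantile))
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return (values < split).astype(int)


def expression_stratified_logrank(table: pd.DataFrame, rule: str = "median") -> LogRankResult:
    """Median-split expression stratification + log-rank in one step."""
    return logrank_test(table, stratify_by_expression(table, rule))
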