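"""Task metrics: AUROC, Harrell's concordance index, Kaplan–Meier curves
and the two-group log-rank test.

Implementations delegate to the field-standard libraries (scikit-learn for
AUROC, lifelines for the survival statistics) behind the package's own
operation surface, which adds the input validation and error contracts the
pipeline relies on. Conventions: AUROC is the Mann–Whitney pair statistic
with ties counted 1/2; the c-index counts comparable pairs under right
censoring with risk ties at 1/2; log-rank p-values are two-sided from the
chi-square(1) tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalRecord", "auroc", "concordance_index", "km_curve",
           "logrank_test"]


@dataclass
class SurvivalRecord:
    time: float
    event: int
    group: str = ""

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _split_records(records):
    """Accept a sequence of SurvivalRecord or a (time, event) DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records["time"].to_numpy(float), records["event"].to_numpy(int)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def auroc(scores, labels) -> float:
    """Area under the ROC curve (probability a positive outscores a
    negative, ties 1/2). Requires both classes present."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def concordance_index(records, risk_scores) -> float:
    """Harrell's c-index of risk scores against right-censored outcomes.

    A pair is comparable when the earlier time is an observed event; it is
    concordant when that earlier-failing sample carries the higher risk
    score, with risk ties counted 1/2. Raises when no comparable pair exists.
    """
    from lifelines.utils import concordance_index as _ci

    times, events = _split_records(records)
    risk = np.asarray(risk_scores, dtype=float)
    if risk.size != times.size:
        raise ValueError("risk_scores must align with records")
    # comparable pair existence check
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    comparable = any(
        e[i] == 1 and (t[j] > t[i] or (t[j] == t[i] and e[j] == 0))
        for i in range(len(t)) for j in range(len(t)) if j != i)
    if not comparable:
        raise ValueError("no comparable pairs under the censoring pattern")
    # lifelines orients concordance toward higher predicted survival times;
    # pass negated risk so higher risk ~ earlier failure counts as concordant
    return float(_ci(times, -risk, events))


def km_curve(records) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate.

    Returns a DataFrame with columns ``time`` and ``survival``: S(0) = 1 and
    one step per distinct event time (right-continuous, non-increasing).
    """
    from lifelines import KaplanMeierFitter

    times, events = _split_records(records)
    if times.size == 0:
        raise ValueError("km_curve needs at least one record")
    km = KaplanMeierFitter()
    km.fit(times, events)
    sf = km.survival_function_
    out = pd.DataFrame({"time": sf.index.to_numpy(float),
                        "survival": sf.iloc[:, 0].to_numpy(float)})
    # keep t=0 and event-time steps only (drop censoring-only rows)
    event_times = np.unique(times[events == 1])
    keep = np.isin(out["time"].to_numpy(), event_times) | (out["time"].to_numpy() == 0.0)
    return out[keep].reset_index(drop=True)


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square statistic, two-sided p).

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation; the statistic is (O-E)^2 / V on
    1 df. Raises when the variance is zero (no events)."""
    from lifelines.statistics import logrank_test as _lr

    t_a, e_a = _split_records(group_a)
    t_b, e_b = _split_records(group_b)
    if e_a.sum() + e_b.sum() == 0:
        raise ValueError("log-rank test undefined without events")
    res = _lr(t_a, t_b, event_observed_A=e_a, event_observed_B=e_b)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        raise ValueError("log-rank variance is zero")
    return stat, p
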