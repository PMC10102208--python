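"""Independent brute-force reference implementations of the metrics.

These enumerate pairs / accumulate the defining tables directly and exist
only to cross-check the package implementations on small instances.
"""

import numpy as np
from scipy.stats import chi2


def brute_auroc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_cindex(times, events, risks):
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risks = np.asarray(risks, float)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # comparable: i fails first (observed event strictly earlier),
            # or i fails at a time where j is censored at the same time
            if events[i] == 1 and (times[i] < times[j]
                                   or (times[i] == times[j] and events[j] == 0)):
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_km(times, events):
    """Product-limit estimate at each distinct event time: [(t, S(t)), ...]
    with the S(0)=1 anchor first."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = [(0.0, 1.0)]
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out.append((float(t), float(s)))
    return out


def brute_logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank via explicit O/E/V accumulation."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    o_a = e_a = v = 0.0
    for t in np.unique(all_t[all_e == 1]):
        n_a = np.sum(ta >= t)
        n_b = np.sum(tb >= t)
        n = n_a + n_b
        d = np.sum((all_t == t) & (all_e == 1))
        d_a = np.sum((ta == t) & (ea == 1))
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if v == 0:
        raise ValueError("zero variance")
    stat = (o_a - e_a) ** 2 / v
    return stat, float(chi2.sf(stat, 1))
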