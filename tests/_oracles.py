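"""Independent brute-force oracles used to validate the package implementations.

Everything here is written for clarity over speed and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import numpy as np


def brute_concordance(risk, time, event) -> float:
    """Harrell's C by explicit pair enumeration.

    Pair (i, j) is usable when min(time) belongs to a subject with an event
    and the times differ; credit 1 if the earlier subject has strictly higher
    risk, 0.5 on a risk tie.
    """
    risk, time, event = (np.asarray(a, dtype=float) for a in (risk, time, event))
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j] or event[i] != 1:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def brute_youden(scores, labels) -> tuple[float, float]:
    """Exhaustive Youden scan over midpoints of sorted unique scores plus
    sentinels, classifying score >= threshold as positive; ties broken toward
    the larger sensitivity."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    uniq = np.unique(s)
    thresholds = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best_j, best_t, best_sens = -np.inf, np.nan, -1.0
    for t in thresholds:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sens > best_sens):
            best_j, best_t, best_sens = j, t, sens
    return float(best_t), float(best_j)


def brute_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct definition: adj_i = min over
    j >= rank(i) of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for k in range(m - 1, -1, -1):
        running = min(running, p[order[k]] * m / (k + 1))
        adj_sorted[k] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def brute_cutpoint(marker, time, event, minprop=0.1):
    """Maximally selected cut-point by a double loop: every observed marker
    value as threshold, standardized two-group log-rank recomputed from its
    textbook definition at each one."""
    marker, time, event = (np.asarray(a, dtype=float) for a in (marker, time, event))
    n = len(time)
    best = (None, -np.inf)
    for c in np.unique(marker)[:-1]:
        high = marker > c
        k = min(high.sum(), n - high.sum())
        if not k / n > minprop:
            continue
        o_minus_e = 0.0
        v = 0.0
        for t in np.unique(time[event == 1]):
            at_risk = time >= t
            n_at = at_risk.sum()
            n1 = (at_risk & high).sum()
            d = ((time == t) & (event == 1)).sum()
            d1 = ((time == t) & (event == 1) & high).sum()
            o_minus_e += d1 - d * n1 / n_at
            if n_at > 1:
                v += d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1)
        if v <= 0:
            continue
        z = abs(o_minus_e) / np.sqrt(v)
        if z > best[1] + 1e-12:
            best = (float(c), float(z))
    if best[0] is None:
        raise ValueError("no admissible split")
    return best


def random_censored_fixture(rng, n):
    """A random survival fixture with ties in times and risks."""
    time = rng.integers(1, 20, size=n).astype(float)
    event = rng.integers(0, 2, size=n)
    risk = rng.integers(0, 6, size=n).astype(float)
    if not ((event == 1) & (time < time.max())).any():
        event[np.argmin(time)] = 1
    return risk, time, event
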