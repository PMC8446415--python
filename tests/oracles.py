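"""Independent brute-force oracles used to check the package numerics.

Everything here is written directly from textbook definitions — naive
loops, explicit enumeration, numerical maximization — deliberately
sharing no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy import optimize


def naive_efron_loglik(beta, z, time, event):
    """Efron log partial likelihood written out with explicit loops."""
    z = np.asarray(z, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.atleast_2d(np.outer(np.atleast_1d(beta), z))  # params x n
    total = np.zeros(lp.shape[0])
    for t in sorted(set(time[event == 1])):
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        m = len(deaths)
        for k, b in enumerate(np.atleast_1d(beta)):
            s_risk = sum(np.exp(b * z[i]) for i in risk)
            s_tie = sum(np.exp(b * z[i]) for i in deaths)
            ll = sum(b * z[i] for i in deaths)
            for ell in range(m):
                ll -= np.log(s_risk - ell / m * s_tie)
            total[k] += ll
    return total if np.ndim(beta) else float(total[0])


def brute_force_cox_beta(z, time, event, bracket=(-20.0, 20.0)):
    """Maximize the written-out Efron partial likelihood numerically."""
    res = optimize.minimize_scalar(
        lambda b: -naive_efron_loglik(b, z, time, event),
        bounds=bracket,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)


def logrank_oracle(time, event, group):
    """Textbook log-rank chi-square by observed-minus-expected tabulation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()), key=str)
    assert len(levels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == levels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == levels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return float(chi2)


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values, textbook step-up procedure."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by full enumeration of assignments."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    nx = len(x)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank[v] for v in x)
    mean_w = nx * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for subset in combinations(pooled, nx):
        w = sum(rank[v] for v in subset)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def empirical_roc(scores, labels):
    """Plain confusion-matrix ROC for a binary outcome, no censoring.

    Positive prediction means score strictly above the threshold; returns
    (thresholds desc, tpr, fpr, auc-by-trapezoid).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = [np.inf] + sorted(set(scores), reverse=True) + [-np.inf]
    tpr, fpr = [], []
    for c in thresholds:
        pred = scores > c
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        tpr.append(tp / max(labels.sum(), 1))
        fpr.append(fp / max((1 - labels).sum(), 1))
    auc = 0.0
    for i in range(1, len(thresholds)):
        auc += (fpr[i] - fpr[i - 1]) * (tpr[i] + tpr[i - 1]) / 2
    return np.array(thresholds), np.array(tpr), np.array(fpr), float(auc)


def pearson_oracle(x, y):
    """Pearson correlation from the raw definition."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def average_ranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and v[order[j]] == v[order[i]]:
            j += 1
        avg = (i + j + 1) / 2  # mean of ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as Pearson on average (tie-corrected) ranks."""
    return pearson_oracle(average_ranks(list(x)), average_ranks(list(y)))


def chi2_oracle(table):
    """Pearson chi-square from sum((O-E)^2 / E)."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            chi2 += (table[i, j] - e) ** 2 / e
    return float(chi2)


def moderated_t_oracle(x1, x0, df_prior, var_prior):
    """Moderated t from the published empirical-Bayes definition, per gene."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    diff = x1.mean(axis=1) - x0.mean(axis=1)
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)) / (
        n1 + n0 - 2
    )
    s2_post = (df_prior * var_prior + (n1 + n0 - 2) * s2) / (df_prior + n1 + n0 - 2)
    return diff / np.sqrt(s2_post * (1 / n1 + 1 / n0))


def km_empirical(time):
    """Empirical survival function (no censoring): S(t) = #{T > t}/n."""
    time = np.asarray(time, dtype=float)

    def s(t):
        return float((time > t).mean())

    return s
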