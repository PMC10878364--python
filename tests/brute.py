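"""Brute-force reference implementation of the CPM protocol.

Explicit Python loops and textbook formulas only — deliberately independent
of the package's vectorized engine so it can serve as an oracle at small n.
"""

import math

import numpy as np
from scipy import stats


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    if vx == 0 or vy == 0:
        return 0.0
    return num / math.sqrt(vx * vy)


def brute_corr_p(x, y):
    n = len(x)
    r = brute_pearson(x, y)
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), n - 2)


def brute_sd(v):
    n = len(v)
    m = sum(v) / n
    return math.sqrt(sum((x - m) ** 2 for x in v) / (n - 1))


def brute_fit_predict(strengths, scores, s_test):
    """Normalize with training parameters, OLS in normalized space, predict."""
    mu_s = sum(strengths) / len(strengths)
    sd_s = brute_sd(strengths)
    mu_y = sum(scores) / len(scores)
    sd_y = brute_sd(scores)
    if sd_s <= 1e-12:
        return mu_y
    zs = [(s - mu_s) / sd_s for s in strengths]
    zy = [(v - mu_y) / sd_y for v in scores]
    mzs = sum(zs) / len(zs)
    mzy = sum(zy) / len(zy)
    num = sum((a - mzs) * b for a, b in zip(zs, zy))
    den = sum((a - mzs) ** 2 for a in zs)
    slope = num / den
    intercept = mzy - slope * mzs
    z_test = (s_test - mu_s) / sd_s
    return (slope * z_test + intercept) * sd_y + mu_y


def brute_loocv(X, y, threshold):
    """Leave-one-out CPM by explicit loops; returns per-sign predictions+masks."""
    n, E = X.shape
    predicted = {"positive": np.empty(n), "negative": np.empty(n)}
    masks = {"positive": np.zeros((n, E), bool), "negative": np.zeros((n, E), bool)}
    for i in range(n):
        train = [j for j in range(n) if j != i]
        pos, neg = [], []
        for e in range(E):
            r, p = brute_corr_p([X[j, e] for j in train], [y[j] for j in train])
            if p < threshold and r > 0:
                pos.append(e)
            elif p < threshold and r < 0:
                neg.append(e)
        for sign, sel in (("positive", pos), ("negative", neg)):
            masks[sign][i, sel] = True
            strengths = [sum(X[j, e] for e in sel) for j in train]
            s_test = sum(X[i, e] for e in sel)
            predicted[sign][i] = brute_fit_predict(
                strengths, [y[j] for j in train], s_test)
    return predicted, masks


def brute_evaluate(predicted, observed):
    return brute_pearson(list(predicted), list(observed))


def brute_permutation_test(X, y, observed_r, threshold, n_permutations, seed):
    """Same permutation stream as the package: default_rng(seed).permutation."""
    rng = np.random.default_rng(seed)
    null = {"positive": [], "negative": []}
    n = len(y)
    for _ in range(n_permutations):
        y_perm = y[rng.permutation(n)]
        predicted, _ = brute_loocv(X, y_perm, threshold)
        for sign in null:
            null[sign].append(brute_evaluate(predicted[sign], y_perm))
    out = {}
    for sign, obs in observed_r.items():
        b = sum(1 for v in null[sign] if v >= obs)
        out[sign] = (b + 1) / (n_permutations + 1)
    return out, null
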