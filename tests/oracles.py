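"""Brute-force reference implementations used only to check the package.

These deliberately use the most literal formulation of each definition
(explicit average ranks, per-position sort-and-median, all-pairs sums) and
stay independent of the implementations they verify.
"""

import math

import numpy as np
from scipy import stats


def average_ranks(v):
    """Average ranks computed by explicit tie-group bookkeeping."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # mean of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def product_moment(x, y):
    """Pearson r by the raw sums formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def t_two_sided_p(r, n):
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return 2.0 * float(stats.t.sf(abs(t), n - 2))


def naive_pearson(x, y):
    r = product_moment(x, y)
    return r, t_two_sided_p(r, len(x))


def naive_spearman(x, y):
    rx = average_ranks(x)
    ry = average_ranks(y)
    r = product_moment(rx, ry)
    return r, t_two_sided_p(r, len(x))


def naive_welch(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, p


def naive_running_median(values, window):
    """Per-position sort-and-take-median with edge truncation."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    left = (window - 1) // 2
    right = window // 2
    out = np.empty(n)
    for i in range(n):
        chunk = sorted(values[max(0, i - left): min(n, i + right + 1)])
        m = len(chunk)
        if m % 2:
            out[i] = chunk[m // 2]
        else:
            out[i] = 0.5 * (chunk[m // 2 - 1] + chunk[m // 2])
    return out


def naive_bin_sizes(n, k):
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]
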