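"""Naive brute-force reference implementations used as independent oracles.

Everything here is written as plain double loops over explicitly built
windows, independent of the package's vectorized/compiled code paths, and
is only ever run on short inputs.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import norm


def chebyshev(u, v) -> float:
    return max(abs(a - b) for a, b in zip(u, v))


def univariate_sample_entropy(x, m: int, d: int, r: float) -> float:
    """SampEn with template count over i = 1..N-m*d at both dimensions."""
    x = list(map(float, x))
    n = m * d
    count = len(x) - n

    def phi(width: int) -> float:
        vecs = [[x[i + l * d] for l in range(width)] for i in range(count)]
        acc = 0.0
        for i in range(count):
            hits = sum(
                1 for j in range(count) if j != i and chebyshev(vecs[i], vecs[j]) <= r
            )
            acc += hits / (count - 1)
        return acc / count

    lo, hi = phi(m), phi(m + 1)
    if lo == 0 or hi == 0:
        return float("nan")
    return -math.log(hi / lo)


def fuzzy_weight(dist: float, r: float, lam: float = 1.0) -> float:
    if dist <= lam * r:
        return 1.0
    return math.exp(-math.log(2.0) * ((dist - lam * r) / r) ** 2)


def univariate_fuzzy_entropy(x, m: int, d: int, r: float, lam: float = 1.0) -> float:
    x = list(map(float, x))
    n = m * d
    count = len(x) - n

    def phi(width: int) -> float:
        vecs = [[x[i + l * d] for l in range(width)] for i in range(count)]
        acc = 0.0
        for i in range(count):
            sims = sum(
                fuzzy_weight(chebyshev(vecs[i], vecs[j]), r, lam)
                for j in range(count)
                if j != i
            )
            acc += sims / (count - 1)
        return acc / count

    return -math.log(phi(m + 1) / phi(m))


def univariate_permutation_entropy(x, m: int, d: int) -> float:
    x = list(map(float, x))
    count = len(x) - (m - 1) * d
    patterns = {}
    for i in range(count):
        window = [x[i + l * d] for l in range(m)]
        # stable argsort: earlier index wins ties
        order = tuple(sorted(range(m), key=lambda l: (window[l], l)))
        patterns[order] = patterns.get(order, 0) + 1
    total = sum(patterns.values())
    return -sum((c / total) * math.log(c / total) for c in patterns.values())


def univariate_dispersion_entropy(x, m: int, d: int, c: int) -> float:
    x = np.asarray(x, dtype=float)
    y = norm.cdf((x - x.mean()) / x.std(ddof=1))
    z = [min(c, max(1, math.floor(c * v + 0.5 + 0.5))) for v in y]
    count = len(z) - (m - 1) * d
    patterns = {}
    for i in range(count):
        pat = tuple(z[i + l * d] for l in range(m))
        patterns[pat] = patterns.get(pat, 0) + 1
    total = sum(patterns.values())
    return -sum((k / total) * math.log(k / total) for k in patterns.values())


def increment_word(window, R: int):
    window = list(map(float, window))
    n = len(window)
    if n > 1:
        mean = sum(window) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in window) / (n - 1))
    else:
        sd = 0.0
    word = []
    for z in window:
        sign = (z > 0) - (z < 0)
        q = 0 if sd == 0 else min(R, math.floor(abs(z) * R / sd))
        word.append((sign, q))
    return tuple(word)


def univariate_increment_entropy(x, m: int, d: int, R: int) -> float:
    x = list(map(float, x))
    inc = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    count = len(inc) - (m - 1) * d
    words = {}
    for i in range(count):
        w = increment_word([inc[i + l * d] for l in range(m)], R)
        words[w] = words.get(w, 0) + 1
    total = sum(words.values())
    return -sum((k / total) * math.log(k / total) for k in words.values())


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjustment (cumulative minimum form)."""
    p = list(map(float, pvals))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, p[i] * n / rank_from_top)
        adj[i] = value
        prev = value
    return adj


def psd_slope(x, fs: float = 1.0) -> float:
    """Log-log slope of the Welch PSD, excluding DC."""
    from scipy.signal import welch

    f, pxx = welch(np.asarray(x, dtype=float), fs=fs, nperseg=1024)
    keep = f > 0
    return float(np.polyfit(np.log(f[keep]), np.log(pxx[keep]), 1)[0])
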