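"""Naive, loop-based reimplementations of every scoring function.

These are deliberately unvectorized, direct-from-the-formula versions
used only as oracles in tests.  For the MINE family and the Kraskov
estimator — where no independent library implementation exists in the
environment — they are independently coded second implementations of
the same published algorithms.
"""

from __future__ import annotations

import math

from scipy.special import digamma


def naive_l1(x, y):
    return sum(abs(a - b) for a, b in zip(x, y))


def naive_l2(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def naive_linf(x, y):
    return max(abs(a - b) for a, b in zip(x, y))


def _mean(v):
    return sum(v) / len(v)


def naive_pearson(x, y):
    mx, my = _mean(x), _mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def naive_midranks(v):
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        mid = (i + j + 2) / 2.0  # mean of 1-based positions
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    return ranks


def naive_spearman(x, y):
    return naive_pearson(naive_midranks(x), naive_midranks(y))


def naive_cosine(x, y, center=False):
    if center:
        mx, my = _mean(x), _mean(y)
        x = [a - mx for a in x]
        y = [b - my for b in y]
    num = sum(a * b for a, b in zip(x, y))
    return num / math.sqrt(sum(a * a for a in x) * sum(b * b for b in y))


def _median(v):
    s = sorted(v)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


def naive_bicor(x, y):
    def weighted(v):
        med = _median(v)
        mad = _median([abs(a - med) for a in v])
        if mad == 0:
            return None
        out = []
        for a in v:
            u = (a - med) / (9.0 * mad)
            w = (1 - u * u) ** 2 if abs(u) < 1 else 0.0
            out.append((a - med) * w)
        return out

    a = weighted(x)
    b = weighted(y)
    if a is None or b is None:
        return float("nan")
    num = sum(p * q for p, q in zip(a, b))
    return num / math.sqrt(sum(p * p for p in a) * sum(q * q for q in b))


def _cov(u, v):
    mu, mv = _mean(u), _mean(v)
    return sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)


def naive_gini(x, y, form="mean"):
    rx = naive_midranks(x)
    ry = naive_midranks(y)
    g1 = _cov(x, ry) / _cov(x, rx)
    g2 = _cov(y, rx) / _cov(y, ry)
    if form == "xy":
        return g1
    if form == "yx":
        return g2
    return (g1 + g2) / 2.0


def naive_ks(x, y):
    nx, ny = len(x), len(y)
    sx, sy = sorted(x), sorted(y)
    best = 0.0
    for v in sx + sy:
        fx = sum(1 for a in sx if a <= v) / nx
        fy = sum(1 for b in sy if b <= v) / ny
        best = max(best, abs(fx - fy))
    return best


def _sign(v):
    return 1 if v > 0 else (-1 if v < 0 else 0)


def naive_set_overlap(x, y, threshold, direction="any", normalize=True):
    a = {i for i, v in enumerate(x) if abs(v) > threshold}
    b = {i for i, v in enumerate(y) if abs(v) > threshold}
    matched = a & b
    if direction == "same":
        matched = {i for i in matched if _sign(x[i]) == _sign(y[i])}
    elif direction == "opposite":
        matched = {i for i in matched if _sign(x[i]) != _sign(y[i])}
    if not normalize:
        return float(len(matched))
    union = a | b
    if not union:
        return float("nan")
    return len(matched) / len(union)


def naive_ksg(x, y, k=6):
    """Kraskov algorithm-1 k-NN MI by brute-force distance scans."""
    n = len(x)
    total = 0.0
    for i in range(n):
        dists = sorted(
            max(abs(x[i] - x[j]), abs(y[i] - y[j])) for j in range(n) if j != i
        )
        eps = dists[k - 1]
        # open-interval membership (x_i - eps, x_i + eps), excluding self
        nx = sum(1 for j in range(n)
                 if j != i and x[i] - eps < x[j] < x[i] + eps)
        ny = sum(1 for j in range(n)
                 if j != i and y[i] - eps < y[j] < y[i] + eps)
        total += digamma(nx + 1) + digamma(ny + 1)
    mi = digamma(k) + digamma(n) - total / n
    return max(float(mi), 0.0)


# -- MINE family -----------------------------------------------------------


def _equipartition_naive(vals, k):
    """Greedy near-equal bins over sorted values, ties kept together."""
    n = len(vals)
    order = sorted(range(n), key=lambda i: vals[i])
    assign = [0] * n
    i = 0
    currbin = 0
    binsize = 0
    desired = n / k
    while i < n:
        j = 1
        while i + j < n and vals[order[i + j]] == vals[order[i]]:
            j += 1
        if (
            binsize != 0
            and currbin < k - 1
            and abs(binsize + j - desired) >= abs(binsize - desired)
        ):
            currbin += 1
            binsize = 0
            desired = (n - i) / (k - currbin)
        for t in range(i, i + j):
            assign[order[t]] = currbin
        binsize += j
        i += j
    return assign


def _entropy_bits(counts):
    tot = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / tot
            h -= p * math.log2(p)
    return h


def _optimize_axis_naive(xvals, rows, max_cols, c):
    n = len(xvals)
    q = max(rows) + 1
    k_hat = max(2, c * max_cols)
    order = sorted(range(n), key=lambda i: xvals[i])
    xs = [xvals[i] for i in order]
    rs = [rows[i] for i in order]

    cid = [0] * n
    for i in range(1, n):
        if xs[i] != xs[i - 1] and rs[i] != rs[i - 1]:
            cid[i] = cid[i - 1] + 1
        else:
            cid[i] = cid[i - 1]
    if cid[-1] + 1 > k_hat:
        cid = _equipartition_naive([float(v) for v in cid], k_hat)
    k = cid[-1] + 1

    # cumulative per-row counts at clump boundaries
    cum = [[0] * (k + 1) for _ in range(q)]
    for r, t in zip(rs, cid):
        cum[r][t + 1] += 1
    for r in range(q):
        for t in range(1, k + 1):
            cum[r][t] += cum[r][t - 1]
    npts = [sum(cum[r][t] for r in range(q)) for t in range(k + 1)]
    h_q = _entropy_bits([cum[r][k] for r in range(q)])

    def cost(s, t):
        counts = [cum[r][t] - cum[r][s] for r in range(q)]
        return (npts[t] - npts[s]) * _entropy_bits(counts)

    inf = math.inf
    lmax = min(max_cols, k)
    g = [[inf] * (lmax + 1) for _ in range(k + 1)]
    for t in range(1, k + 1):
        g[t][1] = cost(0, t)
    for l in range(2, lmax + 1):
        for t in range(l, k + 1):
            best = inf
            for s in range(l - 1, t):
                v = g[s][l - 1] + cost(s, t)
                if v < best:
                    best = v
            g[t][l] = best

    out = []
    running = g[k][1]
    for l in range(2, max_cols + 1):
        if l <= lmax and g[k][l] < running:
            running = g[k][l]
        out.append(h_q - running / n)
    return out


def naive_mine(x, y, alpha=0.6, c=15, gmic_p=-1.0):
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    if all(v == x[0] for v in x) or all(v == y[0] for v in y):
        return {"mic": 0.0, "mev": 0.0, "gmic": 0.0}
    b = max(int(n**alpha), 4)
    raw = {}

    def orientation(a, bvals, transpose):
        for nb in range(2, b // 2 + 1):
            max_cols = b // nb
            if max_cols < 2:
                break
            rows = _equipartition_naive(bvals, nb)
            ivals = _optimize_axis_naive(a, rows, max_cols, c)
            for l in range(2, max_cols + 1):
                cell = (nb, l) if transpose else (l, nb)
                v = ivals[l - 2]
                if v > raw.get(cell, -math.inf):
                    raw[cell] = v

    orientation(x, y, False)
    orientation(y, x, True)
    m = {cell: v / math.log2(min(cell)) for cell, v in raw.items()}

    mic = max(m.values())
    mev = max(v for (nx, ny), v in m.items() if nx == 2 or ny == 2)
    cmax = {}
    for nx, ny in m:
        cmax[(nx, ny)] = max(
            m[(px, py)] for px, py in m if px <= nx and py <= ny
        )
    vals = list(cmax.values())
    if gmic_p < 0 and any(v == 0 for v in vals):
        gmic = 0.0
    else:
        gmic = (_mean([v**gmic_p for v in vals])) ** (1.0 / gmic_p)
    return {"mic": mic, "mev": mev, "gmic": gmic}
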