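"""MINE family association statistics (MIC, MEV, GMIC).

The maximal information coefficient explores grids over the scatter of
two variables: for every grid resolution (nx, ny) with nx * ny <= B(n)
= max(n^alpha, 4) it seeks the grid maximising mutual information, and
normalises by log2(min(nx, ny)) to obtain the characteristic matrix M.
MIC is the maximum entry of M; MEV (maximum edge value) restricts the
maximum to one-dimensional grids (nx = 2 or ny = 2); GMIC replaces the
maximum by a generalized (power) mean, here with exponent p = -1, of
the cumulative maxima of M over the admissible region.

The grid search follows the standard heuristic: one axis is
equipartitioned, the other optimised by dynamic programming over clump
boundaries (runs of consecutive points sharing an equipartition row),
capped at c * nx candidate "superclumps".  Both axis orientations are
evaluated and the better one kept per cell.

All logarithms are base 2.  Complexity is O(B^2 * c^2) per pair, so
this family is orders of magnitude slower than a correlation; it is
meant for reduced gene sets.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["mine_stats", "characteristic_matrix"]

DEFAULT_ALPHA = 0.6
DEFAULT_C = 15


def _equipartition(vals: np.ndarray, k: int) -> np.ndarray:
    """Assign each point to one of <= k bins, near-equal counts.

    Bins are contiguous in sorted order and tied values always share a
    bin.  Returns the bin id per point, aligned with ``vals`` order.
    """
    n = len(vals)
    order = np.argsort(vals, kind="mergesort")
    sv = vals[order]
    assign = np.empty(n, dtype=np.int64)
    i = 0
    currbin = 0
    binsize = 0
    desired = n / k
    while i < n:
        j = 1
        while i + j < n and sv[i + j] == sv[i]:
            j += 1
        if (
            binsize != 0
            and currbin < k - 1
            and abs(binsize + j - desired) >= abs(binsize - desired)
        ):
            currbin += 1
            binsize = 0
            desired = (n - i) / (k - currbin)
        assign[order[i : i + j]] = currbin
        binsize += j
        i += j
    return assign


def _clumps_sorted(xs: np.ndarray, rs: np.ndarray, k_hat: int) -> np.ndarray:
    """Clump id per point, inputs already x-sorted.

    A new clump starts where the x value changes AND the row label
    changes; x-ties are never split.  If more than ``k_hat`` clumps
    result, they are merged into ``k_hat`` superclumps of near-equal
    point counts (equipartition of the clump ids, which keeps whole
    clumps together).
    """
    n = len(xs)
    cid = np.empty(n, dtype=np.int64)
    cid[0] = 0
    for i in range(1, n):
        if xs[i] != xs[i - 1] and rs[i] != rs[i - 1]:
            cid[i] = cid[i - 1] + 1
        else:
            cid[i] = cid[i - 1]
    if cid[-1] + 1 > k_hat:
        cid = _equipartition(cid.astype(float), k_hat)
    return cid


def _entropy_from_counts(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _optimize_axis(x: np.ndarray, rows: np.ndarray, max_cols: int, c: int) -> np.ndarray:
    """Best mutual information for 2..max_cols columns on the x axis.

    ``rows`` is the fixed equipartition of the other axis.  Returns an
    array I[l] for l = 2..max_cols (index 0 -> 2 columns), where I[l]
    is the maximum over column partitions with at most l columns whose
    boundaries fall on clump edges.
    """
    n = len(x)
    q = int(rows.max()) + 1
    k_hat = max(2, c * max_cols)
    order = np.argsort(x, kind="mergesort")
    cs = _clumps_sorted(x[order], rows[order], k_hat)
    rs = rows[order]
    k = int(cs[-1]) + 1

    # cumulative per-row counts at clump boundaries: cum[r, t] = #points
    # with row r in clumps 0..t-1
    cum = np.zeros((q, k + 1), dtype=np.int64)
    for r, t in zip(rs, cs):
        cum[r, t + 1] += 1
    cum = np.cumsum(cum, axis=1)
    npts = cum.sum(axis=0)  # points in clumps 0..t-1

    h_q = _entropy_from_counts(cum[:, k])

    # w[s, t] = n_(s,t] * H(rows in clumps s..t-1], an additive cost term;
    # n*H = n*log2(n) - sum_r c_r*log2(c_r)
    diff = cum[:, None, :] - cum[:, :, None]  # (q, s, t) per-row counts in (s, t]
    tot = npts[None, :] - npts[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        clog = np.where(diff > 0, diff * np.log2(np.maximum(diff, 1)), 0.0).sum(axis=0)
        w = np.where(tot > 0, tot * np.log2(np.maximum(tot, 1)) - clog, 0.0)

    # g[t, l] = min cost of partitioning clumps 0..t-1 into exactly l columns
    inf = math.inf
    lmax = min(max_cols, k)
    g = np.full((k + 1, lmax + 1), inf)
    g[1:, 1] = w[0, 1:]
    for l in range(2, lmax + 1):
        for t in range(l, k + 1):
            g[t, l] = np.min(g[l - 1 : t, l - 1] + w[l - 1 : t, t])

    out = np.empty(max_cols - 1)
    running = g[k, 1]
    for l in range(2, max_cols + 1):
        if l <= lmax and g[k, l] < running:
            running = g[k, l]
        out[l - 2] = h_q - running / n
    return out


def characteristic_matrix(
    x: np.ndarray, y: np.ndarray, alpha: float = DEFAULT_ALPHA, c: int = DEFAULT_C
) -> dict[tuple[int, int], float]:
    """Normalised characteristic matrix over {(nx, ny): nx,ny >= 2, nx*ny <= B}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 4:
        raise ValueError("need at least 4 points")
    b = max(int(n**alpha), 4)

    raw: dict[tuple[int, int], float] = {}

    def one_orientation(a, bvals, transpose: bool):
        # equipartition `bvals` into nb rows, optimise `a` axis
        for nb in range(2, b // 2 + 1):
            max_cols = b // nb
            if max_cols < 2:
                break
            rows = _equipartition(bvals, nb)
            ivals = _optimize_axis(a, rows, max_cols, c)
            for l in range(2, max_cols + 1):
                cell = (nb, l) if transpose else (l, nb)
                v = ivals[l - 2]
                if v > raw.get(cell, -math.inf):
                    raw[cell] = v

    one_orientation(x, y, transpose=False)
    one_orientation(y, x, transpose=True)

    return {
        (nx, ny): v / math.log2(min(nx, ny)) for (nx, ny), v in raw.items()
    }


def mine_stats(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    c: int = DEFAULT_C,
    gmic_p: float = -1.0,
) -> dict[str, float]:
    """Compute MIC, MEV and GMIC for one pair of vectors.

    Constant input has no association structure: all statistics are 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"mic": 0.0, "mev": 0.0, "gmic": 0.0}
    m = characteristic_matrix(x, y, alpha=alpha, c=c)
    mic = max(m.values())
    mev = max(v for (nx, ny), v in m.items() if nx == 2 or ny == 2)

    # cumulative maxima over the admissible region, then a power mean
    cells = sorted(m)
    cmax = {}
    for nx, ny in cells:
        best = m[(nx, ny)]
        for px, py in cells:
            if px <= nx and py <= ny and m[(px, py)] > best:
                best = m[(px, py)]
        cmax[(nx, ny)] = best
    vals = np.array(list(cmax.values()))
    if gmic_p == 0:
        gmic = float(np.exp(np.mean(np.log(np.maximum(vals, 1e-300)))))
    elif gmic_p < 0 and np.any(vals == 0):
        gmic = 0.0
    else:
        gmic = float(np.mean(vals**gmic_p) ** (1.0 / gmic_p))
    return {"mic": float(mic), "mev": float(mev), "gmic": gmic}
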