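"""Low-level MINE kernels: equipartition, clumps, and the column-optimizing DP.

These routines implement the approximate characteristic-matrix construction
for the maximal information coefficient: one axis is equipartitioned into a
fixed number of rows, and the partition of the other axis is optimized by a
dynamic program over "clumps" (maximal runs of consecutive points sharing a
row, never splitting tied values). When the number of clumps exceeds the
budget c*k, clumps are first merged into mass-equipartitioned superclumps.

All entropies use natural logarithms; normalized quantities are ratios of
logarithms, so the base cancels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["half_characteristic_matrix", "grid_budget"]


def grid_budget(n: int, alpha: float) -> int:
    """Grid-size budget B(n) = ceil(n**alpha); shapes (k, l) with k*l <= B."""
    return int(np.ceil(n**alpha))


@njit(cache=True)
def _equipartition(vals_sorted, n_rows):
    """Assign sorted values to ``n_rows`` rows of near-equal size.

    Tied values are never split across rows. Returns (row id per sorted
    position, number of rows actually used). The number of used rows can be
    smaller than requested when large tie groups dominate.
    """
    n = vals_sorted.shape[0]
    rows = np.zeros(n, dtype=np.int64)
    desired = n / n_rows
    curr_row = 0
    curr_size = 0.0
    i = 0
    while i < n:
        j = i + 1
        while j < n and vals_sorted[j] == vals_sorted[i]:
            j += 1
        s = j - i
        if curr_size > 0.0 and curr_row < n_rows - 1:
            if abs(curr_size + s - desired) >= abs(curr_size - desired):
                curr_row += 1
                curr_size = 0.0
                desired = (n - i) / (n_rows - curr_row)
        for t in range(i, j):
            rows[t] = curr_row
        curr_size += s
        i = j
    return rows, curr_row + 1


@njit(cache=True)
def _clump_ids(x_sorted, rows_x_order):
    """Group points (sorted by x) into clumps.

    A clump is a maximal run of consecutive points lying in the same row;
    points with identical x form an indivisible block, and a block spanning
    several rows becomes its own clump. Returns a nondecreasing clump id per
    point.
    """
    n = x_sorted.shape[0]
    labels = np.empty(n, dtype=np.int64)
    special = -1
    i = 0
    while i < n:
        j = i + 1
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        r0 = rows_x_order[i]
        mixed = False
        for t in range(i + 1, j):
            if rows_x_order[t] != r0:
                mixed = True
                break
        if mixed:
            for t in range(i, j):
                labels[t] = special
            special -= 2  # unique negative label per mixed block
        else:
            for t in range(i, j):
                labels[t] = r0
        i = j
    ids = np.empty(n, dtype=np.int64)
    cid = 0
    ids[0] = 0
    for t in range(1, n):
        if labels[t] != labels[t - 1]:
            cid += 1
        ids[t] = cid
    return ids


@njit(cache=True)
def _cum_rows(group_ids, rows_x_order, n_rows):
    """Cumulative per-row point counts at group boundaries: shape (p+1, n_rows)."""
    n = group_ids.shape[0]
    p = group_ids[n - 1] + 1
    cum = np.zeros((p + 1, n_rows), dtype=np.float64)
    for t in range(n):
        gid = group_ids[t]
        cum[gid + 1, rows_x_order[t]] += 1.0
    for g in range(1, p + 1):
        for r in range(n_rows):
            cum[g, r] += cum[g - 1, r]
    return cum


@njit(cache=True)
def _optimize_columns(cum, kmax):
    """Best prefix score F(p, k) for k = 1..kmax column partitions.

    F(t, k) = max over partitions of the first t clumps into k columns of
    H(P) - H(P, Q), computed on the prefix normalized to its own mass; for
    the full data (t = p) adding H(Q) yields the mutual information.
    """
    p = cum.shape[0] - 1
    n_rows = cum.shape[1]
    csum = np.empty(p + 1, dtype=np.float64)
    for t in range(p + 1):
        s = 0.0
        for r in range(n_rows):
            s += cum[t, r]
        csum[t] = s
    kk = min(kmax, p)
    F = np.full((p + 1, kk + 1), -np.inf)
    for t in range(1, p + 1):
        v = 0.0
        ct = csum[t]
        for r in range(n_rows):
            m = cum[t, r]
            if m > 0.0:
                v += (m / ct) * np.log(m / ct)
        F[t, 1] = v
    for k in range(2, kk + 1):
        for t in range(k, p + 1):
            ct = csum[t]
            best = -np.inf
            for s in range(k - 1, t):
                val = (csum[s] / ct) * F[s, k - 1]
                m = ct - csum[s]
                val -= (m / ct) * np.log(m / ct)
                for r in range(n_rows):
                    mr = cum[t, r] - cum[s, r]
                    if mr > 0.0:
                        val += (mr / ct) * np.log(mr / ct)
                if val > best:
                    best = val
            F[t, k] = best
    out = np.empty(kk, dtype=np.float64)
    for k in range(1, kk + 1):
        out[k - 1] = F[p, k]
    return out


def half_characteristic_matrix(x: np.ndarray, y: np.ndarray, B: int, c: float) -> np.ndarray:
    """Normalized MI for every shape, equipartitioning y and optimizing x.

    Returns a (B//2 + 1, B//2 + 1) array M with M[k, l] filled for
    2 <= k, l and k*l <= B (NaN elsewhere): the maximal mutual information
    over grids with at most k columns and l equipartitioned rows, normalized
    by log(min(k, l)).
    """
    n = x.shape[0]
    half = B // 2
    M = np.full((half + 1, half + 1), np.nan)
    oy = np.argsort(y, kind="stable")
    ox = np.argsort(x, kind="stable")
    x_sorted = np.asarray(x, dtype=np.float64)[ox]
    y_sorted = np.asarray(y, dtype=np.float64)[oy]
    rows_by_point = np.empty(n, dtype=np.int64)
    for l in range(2, half + 1):
        kmax = B // l
        if kmax < 2:
            break
        rows_sorted, n_rows = _equipartition(y_sorted, l)
        if n_rows < 2:
            continue  # ties collapse all rows; no information at this l
        rows_by_point[oy] = rows_sorted
        rows_x = rows_by_point[ox]
        cids = _clump_ids(x_sorted, rows_x)
        p = int(cids[-1]) + 1
        khat = max(int(c * kmax), kmax)
        if p > khat:
            sup, _ = _equipartition(cids.astype(np.float64), khat)
            cids = sup
        cum = _cum_rows(cids, rows_x, n_rows)
        tot = cum[-1]
        pos = tot[tot > 0]
        hq = -np.sum((pos / n) * np.log(pos / n))
        fk = _optimize_columns(cum, kmax)
        run = -np.inf
        for k in range(2, kmax + 1):
            idx = min(k, len(fk)) - 1
            val = fk[idx] + hq
            if val > run:
                run = val
            M[k, l] = run / np.log(min(k, l))
    return M
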