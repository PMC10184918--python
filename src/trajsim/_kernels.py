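"""Jit-compiled dynamic programs shared by the coupling-based measures.

All kernels take a precomputed (n, m) pairwise distance matrix, so the same
code serves Euclidean and geographic metrics.  Value-only kernels use a
two-row rolling table (O(min-side) memory); full-table variants exist for
backtracking witness couplings.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def frechet_dp(d: np.ndarray) -> float:
    """Discrete Fréchet distance: min over monotone couplings of the max pair distance."""
    n, m = d.shape
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = d[0, 0]
    for j in range(1, m):
        prev[j] = max(prev[j - 1], d[0, j])
    for i in range(1, n):
        cur[0] = max(prev[0], d[i, 0])
        for j in range(1, m):
            c = prev[j]
            if prev[j - 1] < c:
                c = prev[j - 1]
            if cur[j - 1] < c:
                c = cur[j - 1]
            cur[j] = c if c > d[i, j] else d[i, j]
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def frechet_full(d: np.ndarray) -> np.ndarray:
    """Full discrete-Fréchet DP table (for coupling backtracking)."""
    n, m = d.shape
    c = np.empty((n, m))
    c[0, 0] = d[0, 0]
    for j in range(1, m):
        c[0, j] = max(c[0, j - 1], d[0, j])
    for i in range(1, n):
        c[i, 0] = max(c[i - 1, 0], d[i, 0])
        for j in range(1, m):
            best = c[i - 1, j]
            if c[i - 1, j - 1] < best:
                best = c[i - 1, j - 1]
            if c[i, j - 1] < best:
                best = c[i, j - 1]
            c[i, j] = best if best > d[i, j] else d[i, j]
    return c


@njit(cache=True)
def dtw_dp(d: np.ndarray) -> float:
    """Dynamic time warping: min over monotone couplings of the sum of pair distances."""
    n, m = d.shape
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = d[0, 0]
    for j in range(1, m):
        prev[j] = prev[j - 1] + d[0, j]
    for i in range(1, n):
        cur[0] = prev[0] + d[i, 0]
        for j in range(1, m):
            c = prev[j]
            if prev[j - 1] < c:
                c = prev[j - 1]
            if cur[j - 1] < c:
                c = cur[j - 1]
            cur[j] = c + d[i, j]
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def dtw_full(d: np.ndarray) -> np.ndarray:
    """Full DTW cost table (for coupling backtracking)."""
    n, m = d.shape
    c = np.empty((n, m))
    c[0, 0] = d[0, 0]
    for j in range(1, m):
        c[0, j] = c[0, j - 1] + d[0, j]
    for i in range(1, n):
        c[i, 0] = c[i - 1, 0] + d[i, 0]
        for j in range(1, m):
            best = c[i - 1, j]
            if c[i - 1, j - 1] < best:
                best = c[i - 1, j - 1]
            if c[i, j - 1] < best:
                best = c[i, j - 1]
            c[i, j] = best + d[i, j]
    return c


@njit(cache=True)
def lcss_dp(d: np.ndarray, epsilon: float, delta: float) -> int:
    """Longest common subsequence count under spatial (ε) and index-time (δ) thresholds.

    match(i, j) iff d[i, j] < epsilon and |i - j| <= delta; pass delta = inf
    for an unbounded time threshold.
    """
    n, m = d.shape
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(n):
        for j in range(m):
            dt = i - j if i >= j else j - i
            if d[i, j] < epsilon and dt <= delta:
                cur[j + 1] = prev[j] + 1
            else:
                a = prev[j + 1]
                b = cur[j]
                cur[j + 1] = a if a > b else b
        prev, cur = cur, prev
        cur[:] = 0
    return prev[m]


@njit(cache=True)
def lcss_contiguous(d: np.ndarray, epsilon: float, delta: float) -> int:
    """Longest common *run* (contiguous common subsequence) under the same thresholds."""
    n, m = d.shape
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    best = 0
    for i in range(n):
        for j in range(m):
            dt = i - j if i >= j else j - i
            if d[i, j] < epsilon and dt <= delta:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best:
                    best = cur[j + 1]
            else:
                cur[j + 1] = 0
        prev, cur = cur, prev
        cur[:] = 0
    return best


@njit(cache=True)
def weak_frechet_dp(d: np.ndarray) -> float:
    """Weak (backtracking-allowed) discrete Fréchet distance.

    Bottleneck shortest path on the n×m grid graph — node (i, j) costs
    d[i, j]; moves change each index by at most 1 in any direction
    (king moves, so diagonal advances and backtracking are both allowed);
    path from (0, 0) to (n-1, m-1) minimizing the maximum node cost.
    Dijkstra with minimax relaxation on a binary heap.  Diagonal moves make
    every monotone coupling a valid path, hence the result never exceeds the
    discrete Fréchet distance.
    """
    n, m = d.shape
    size_total = n * m
    target = size_total - 1
    cap = 8 * size_total + 4  # one heap slot per possible edge relaxation
    hk = np.empty(cap)
    hv = np.empty(cap, np.int64)
    best = np.full(size_total, np.inf)
    done = np.zeros(size_total, np.uint8)
    start_key = d[0, 0]
    if size_total == 1:
        return start_key
    hk[0] = start_key
    hv[0] = 0
    best[0] = start_key
    size = 1
    while size > 0:
        key = hk[0]
        node = hv[0]
        size -= 1
        hk[0] = hk[size]
        hv[0] = hv[size]
        i = 0
        while True:  # sift down
            left = 2 * i + 1
            right = left + 1
            s = i
            if left < size and hk[left] < hk[s]:
                s = left
            if right < size and hk[right] < hk[s]:
                s = right
            if s == i:
                break
            hk[i], hk[s] = hk[s], hk[i]
            hv[i], hv[s] = hv[s], hv[i]
            i = s
        if done[node]:
            continue
        done[node] = 1
        if node == target:
            return key
        ni = node // m
        nj = node % m
        for di in range(-1, 2):
            for dj in range(-1, 2):
                if di == 0 and dj == 0:
                    continue
                ii = ni + di
                jj = nj + dj
                if not (0 <= ii < n and 0 <= jj < m):
                    continue
                nb = ii * m + jj
                if done[nb]:
                    continue
                nk = key if key > d[ii, jj] else d[ii, jj]
                if nk < best[nb]:
                    best[nb] = nk
                    hk[size] = nk
                    hv[size] = nb
                    c = size
                    size += 1
                    while c > 0:  # sift up
                        p = (c - 1) // 2
                        if hk[p] > hk[c]:
                            hk[p], hk[c] = hk[c], hk[p]
                            hv[p], hv[c] = hv[c], hv[p]
                            c = p
                        else:
                            break
    return best[target]
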