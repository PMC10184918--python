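"""Brute-force reference implementations for validating the DP measures.

Everything here is exhaustive and only feasible for tiny inputs; the test
suite compares the fast dynamic programs against these oracles.  None of the
oracles shares code with the implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterator

import numpy as np
from scipy import ndimage

from .geometry import EUCLIDEAN, MetricSpec
from .measures import _coords

__all__ = [
    "enumerate_monotone_couplings",
    "oracle_coupling_search",
    "weak_frechet_oracle",
]

_MAX_SIZE = 7


def enumerate_monotone_couplings(n: int, m: int) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every monotone coupling of an n-element and an m-element trajectory.

    A monotone coupling is a lattice path from (0, 0) to (n-1, m-1) with steps
    (1, 0), (0, 1) or (1, 1); there are Delannoy(n-1, m-1) of them.
    """

    def walk(i: int, j: int, acc: list[tuple[int, int]]):
        if i == n - 1 and j == m - 1:
            yield tuple(acc)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m:
                acc.append((ii, jj))
                yield from walk(ii, jj, acc)
                acc.pop()

    yield from walk(0, 0, [(0, 0)])


def _lcss_brute(d: np.ndarray, epsilon: float, delta: float) -> int:
    """Longest common subsequence by enumerating all index-subsequence pairs."""
    n, m = d.shape
    for k in range(min(n, m), 0, -1):
        for isub in combinations(range(n), k):
            for jsub in combinations(range(m), k):
                if all(
                    d[i, j] < epsilon and abs(i - j) <= delta
                    for i, j in zip(isub, jsub)
                ):
                    return k
    return 0


def oracle_coupling_search(
    p,
    q,
    objective: str,
    params: dict | None = None,
    metric: MetricSpec = EUCLIDEAN,
    max_size: int = _MAX_SIZE,
) -> float:
    """Exhaustive optimum over couplings (or subsequence matchings).

    ``objective``: ``"max"`` (discrete Fréchet), ``"sum"`` (DTW) or
    ``"lcss"`` (raw match count; ``params`` supplies ``epsilon``/``delta``).
    Guarded to n, m <= ``max_size``.
    """
    cp, cq = _coords(p), _coords(q)
    n, m = cp.shape[0], cq.shape[0]
    if n > max_size or m > max_size:
        raise ValueError(f"oracle limited to trajectories of length <= {max_size}")
    d = metric.pairwise(cp, cq)
    if objective == "lcss":
        params = params or {}
        return float(
            _lcss_brute(d, params["epsilon"], params.get("delta", math.inf))
        )
    if objective not in ("max", "sum"):
        raise ValueError(f"unknown objective {objective!r}")
    agg = np.max if objective == "max" else np.sum
    best = math.inf
    for coupling in enumerate_monotone_couplings(n, m):
        cost = agg([d[i, j] for i, j in coupling])
        if cost < best:
            best = cost
    return float(best)


_KING_CONN = np.ones((3, 3), dtype=int)  # index moves of at most 1 in each coordinate


def _connected(d: np.ndarray, threshold: float) -> bool:
    mask = d <= threshold
    if not (mask[0, 0] and mask[-1, -1]):
        return False
    labels, _ = ndimage.label(mask, structure=_KING_CONN)
    return labels[0, 0] == labels[-1, -1]


def weak_frechet_oracle(p, q, metric: MetricSpec = EUCLIDEAN) -> float:
    """Weak Fréchet distance by threshold binary search + grid reachability.

    The answer is the smallest node cost ε for which the ε-thresholded grid
    (king-move connectivity: each index changes by at most 1 per step)
    contains a connected path from (0, 0) to (n-1, m-1); found by binary
    search over the sorted set of node costs, with connectivity checked by
    connected-component labeling.
    """
    d = metric.pairwise(_coords(p), _coords(q))
    costs = np.unique(d)
    lo, hi = 0, len(costs) - 1
    # the endpoints' own costs are a lower bound
    floor = max(d[0, 0], d[-1, -1])
    lo = int(np.searchsorted(costs, floor))
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected(d, costs[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(costs[lo])
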