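"""The eight trajectory-similarity measures.

Bottleneck measures (HD, DFD, DWFD) report the single worst required pairing
distance; aggregated measures (DTW, LCSS, DDM, WD, KLD) accumulate
contributions from every element.  HD, WD, KLD and DDM are order-independent
(they see the trajectory as a point set or distribution); DFD, DWFD, DTW and
LCSS depend on element order.

Every measure returns a :class:`SimilarityResult` whose ``value`` is
non-negative and zero for identical inputs (LCSS reports the normalized
dissimilarity ``1 - count/min(n, m)`` as its value and retains the raw match
count in ``raw``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import rel_entr
from scipy.stats import wasserstein_distance

from . import _kernels
from .geometry import EUCLIDEAN, MetricSpec
from .trajectory import (
    DimensionDistributions,
    StructureEnsemble,
    Trajectory,
    pair_distributions,
)

__all__ = [
    "MEASURE_NAMES",
    "Coupling",
    "LCSSParams",
    "SimilarityResult",
    "DDMResult",
    "hausdorff",
    "discrete_frechet",
    "weak_frechet",
    "dtw",
    "lcss",
    "ddm",
    "wasserstein",
    "kld",
    "compare",
]

#: Table-1 abbreviations, lower-cased.
MEASURE_NAMES = ("hd", "dfd", "dwfd", "dtw", "lcss", "ddm", "wd", "kld")


@dataclass(frozen=True)
class LCSSParams:
    """LCSS thresholds: spatial ε (coordinate units) and index-time δ (elements)."""

    epsilon: float
    delta: float = math.inf

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0 (or inf for unbounded)")


@dataclass
class Coupling:
    """Ordered pairing of element indices between two trajectories.

    A *monotone* coupling (DFD/DTW) starts at (0, 0), ends at (n-1, m-1) and
    advances each index by 0 or 1 per step (not both 0).  A *weak* coupling
    (DWFD) changes each index by at most 1 per step in either direction
    (king moves), allowing backtracking; every monotone coupling is weak.
    """

    pairs: list[tuple[int, int]]

    def is_monotone(self, n: int, m: int) -> bool:
        p = self.pairs
        if not p or p[0] != (0, 0) or p[-1] != (n - 1, m - 1):
            return False
        for (i0, j0), (i1, j1) in zip(p, p[1:]):
            di, dj = i1 - i0, j1 - j0
            if di not in (0, 1) or dj not in (0, 1) or (di == 0 and dj == 0):
                return False
        return True

    def is_weak(self, n: int, m: int) -> bool:
        p = self.pairs
        if not p or p[0] != (0, 0) or p[-1] != (n - 1, m - 1):
            return False
        for (i0, j0), (i1, j1) in zip(p, p[1:]):
            di, dj = abs(i1 - i0), abs(j1 - j0)
            if di > 1 or dj > 1 or (di == 0 and dj == 0):
                return False
        return True


@dataclass
class SimilarityResult:
    """Outcome of one measure on one input pair."""

    measure: str
    value: float
    params: dict = field(default_factory=dict)
    n: int = 0
    m: int = 0
    raw: float | None = None
    coupling: Coupling | None = None


@dataclass
class DDMResult:
    """Difference-distance-matrix outcome: per-site values and the ΔD matrix."""

    per_site: np.ndarray
    diff_matrix: np.ndarray
    mean_distances_a: np.ndarray
    mean_distances_b: np.ndarray

    @property
    def value(self) -> float:
        """Mean of the per-site values: one comparable scalar for the pair."""
        return float(np.mean(self.per_site))


def _coords(x) -> np.ndarray:
    if isinstance(x, Trajectory):
        return x.coords
    c = np.asarray(x, dtype=float)
    if c.ndim == 1:
        c = c.reshape(1, -1)
    if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
        raise ValueError("expected a Trajectory or a non-empty (n, 3) array")
    return c


def _pairwise(p, q, metric: MetricSpec) -> tuple[np.ndarray, int, int]:
    cp, cq = _coords(p), _coords(q)
    d = metric.pairwise(cp, cq)
    return d, cp.shape[0], cq.shape[0]


# ---------------------------------------------------------------------------
# Bottleneck measures


def hausdorff(p, q, metric: MetricSpec = EUCLIDEAN) -> SimilarityResult:
    """Hausdorff distance: the largest closest-neighbor distance between the two element sets."""
    d, n, m = _pairwise(p, q, metric)
    value = max(d.min(axis=1).max(), d.min(axis=0).max())
    return SimilarityResult("hd", float(value), {"metric": metric.name}, n, m)


def _backtrack(table: np.ndarray) -> Coupling:
    """Walk a DP table from (n-1, m-1) back to (0, 0).

    Tie-break: prefer the diagonal predecessor, then the i-predecessor; this
    affects only the witness coupling, never the optimal value.
    """
    i, j = table.shape[0] - 1, table.shape[1] - 1
    pairs = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            cands = ((table[i - 1, j - 1], 0), (table[i - 1, j], 1), (table[i, j - 1], 2))
            best = min(cands)[1]  # ties prefer diagonal, then the i-predecessor
            if best == 0:
                i, j = i - 1, j - 1
            elif best == 1:
                i -= 1
            else:
                j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return Coupling(pairs)


def discrete_frechet(
    p, q, metric: MetricSpec = EUCLIDEAN, return_coupling: bool = False
) -> SimilarityResult:
    """Discrete Fréchet distance: the best worst pairing over monotone couplings.

    The default mode uses a two-row rolling DP table (memory O(min(n, m)));
    ``return_coupling`` keeps the full table and backtracks a witness.
    """
    d, n, m = _pairwise(p, q, metric)
    coupling = None
    if return_coupling:
        table = _kernels.frechet_full(d)
        value = table[-1, -1]
        coupling = _backtrack(table)
    elif m <= n:
        value = _kernels.frechet_dp(d)
    else:
        value = _kernels.frechet_dp(np.ascontiguousarray(d.T))
    return SimilarityResult("dfd", float(value), {"metric": metric.name}, n, m,
                            coupling=coupling)


def weak_frechet(p, q, metric: MetricSpec = EUCLIDEAN) -> SimilarityResult:
    """Weak discrete Fréchet distance: like DFD but traversal may backtrack.

    Computed as the bottleneck (minimax node cost) shortest path on the n×m
    grid graph with king moves (each index changes by at most 1 per step, in
    either direction); never exceeds the DFD value.
    """
    d, n, m = _pairwise(p, q, metric)
    value = _kernels.weak_frechet_dp(d)
    return SimilarityResult("dwfd", float(value), {"metric": metric.name}, n, m)


# ---------------------------------------------------------------------------
# Aggregated measures


def dtw(p, q, metric: MetricSpec = EUCLIDEAN, return_coupling: bool = False,
        band: int | None = None) -> SimilarityResult:
    """Dynamic time warping: the smallest sum of pair distances over monotone couplings.

    Distances are unsquared and unconstrained by default; ``band`` adds an
    optional Sakoe–Chiba window |i - j| <= band.
    """
    d, n, m = _pairwise(p, q, metric)
    if band is not None:
        mask = np.abs(np.subtract.outer(np.arange(n), np.arange(m))) > band
        d = d.copy()
        d[mask] = np.inf
    coupling = None
    if return_coupling:
        table = _kernels.dtw_full(d)
        value = table[-1, -1]
        coupling = _backtrack(table)
    else:
        value = _kernels.dtw_dp(d)
    params = {"metric": metric.name}
    if band is not None:
        params["band"] = band
    return SimilarityResult("dtw", float(value), params, n, m, coupling=coupling)


def lcss(
    p,
    q,
    epsilon: float | None = None,
    delta: float = math.inf,
    metric: MetricSpec = EUCLIDEAN,
    params: LCSSParams | None = None,
    contiguous: bool = False,
) -> SimilarityResult:
    """Longest common subsequence under spatial (ε) and time (δ) thresholds.

    Elements match when their distance is below ε and their indices differ by
    at most δ.  ``value`` is the normalized dissimilarity
    ``1 - count / min(n, m)`` (larger = more different, consistent with the
    other measures); ``raw`` is the match count.  ``contiguous`` switches to
    the longest common *run* variant.
    """
    if params is None:
        if epsilon is None:
            raise ValueError("lcss requires epsilon (or an LCSSParams)")
        params = LCSSParams(epsilon, delta)
    d, n, m = _pairwise(p, q, metric)
    kern = _kernels.lcss_contiguous if contiguous else _kernels.lcss_dp
    count = int(kern(d, params.epsilon, params.delta))
    value = 1.0 - count / min(n, m)
    meta = {"epsilon": params.epsilon, "delta": params.delta, "metric": metric.name,
            "contiguous": contiguous}
    return SimilarityResult("lcss", float(value), meta, n, m, raw=count)


def ddm(a: StructureEnsemble, b: StructureEnsemble, signed: bool = False) -> DDMResult:
    """Difference distance matrix between two structure ensembles.

    Within each ensemble the time-averaged pairwise site-distance matrix is
    formed; their element-wise difference Δ = D_A − D_B quantifies the change
    in internal displacement.  The per-site value is the column mean of |Δ|
    (``signed=False``, default — signed means can cancel and hide
    displacement) or of Δ (``signed=True``).  Rigid motions of either
    ensemble leave the result unchanged.
    """
    if a.n_sites != b.n_sites:
        raise ValueError(f"site count mismatch: {a.n_sites} vs {b.n_sites}")

    def mean_dist(e: StructureEnsemble) -> np.ndarray:
        acc = np.zeros((e.n_sites, e.n_sites))
        for t in range(e.n_frames):
            acc += cdist(e.coords[t], e.coords[t])
        return acc / e.n_frames

    da, db = mean_dist(a), mean_dist(b)
    diff = da - db
    per_site = diff.mean(axis=1) if signed else np.abs(diff).mean(axis=1)
    return DDMResult(per_site, diff, da, db)


def _as_distributions(p, q, bins: int) -> tuple[DimensionDistributions, DimensionDistributions]:
    if isinstance(p, DimensionDistributions) and isinstance(q, DimensionDistributions):
        return p, q
    if isinstance(p, DimensionDistributions) or isinstance(q, DimensionDistributions):
        raise TypeError("give either two trajectories or two DimensionDistributions")
    return pair_distributions(p, q, bins=bins)


def wasserstein(p, q, bins: int = 100) -> SimilarityResult:
    """Wasserstein (earth mover's) distance, summed over the three spatial axes.

    Each axis term is the exact 1-D 1-Wasserstein distance between the
    empirical samples (CDF-difference integral — no binning involved).
    """
    dp, dq = _as_distributions(p, q, bins)
    value = sum(
        wasserstein_distance(dp.samples[:, ax], dq.samples[:, ax]) for ax in range(3)
    )
    return SimilarityResult("wd", float(value), {}, dp.samples.shape[0], dq.samples.shape[0])


def kld(
    p,
    q,
    pseudocount: float = 1e-10,
    symmetrize: bool = False,
    bins: int = 100,
) -> SimilarityResult:
    """Kullback–Leibler divergence between binned per-axis distributions, in nats.

    Requires both distributions on identical bin edges (trajectory inputs are
    binned on shared edges automatically).  A pseudocount is added to every
    bin and masses renormalized, so empty bins never yield infinities.
    Asymmetric in its arguments unless ``symmetrize`` is set, which returns
    KL(p‖q) + KL(q‖p).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    dp, dq = _as_distributions(p, q, bins)
    if dp.masses is None or dq.masses is None:
        raise ValueError("kld needs binned distributions")
    if dp.masses.shape != dq.masses.shape or not np.allclose(
        dp.bin_edges, dq.bin_edges, atol=0, rtol=1e-12
    ):
        raise ValueError("kld requires identical bin edges for both inputs")

    def smooth(masses: np.ndarray) -> np.ndarray:
        s = masses + pseudocount
        return s / s.sum(axis=1, keepdims=True)

    pm, qm = smooth(dp.masses), smooth(dq.masses)
    forward = float(rel_entr(pm, qm).sum())
    value = forward + float(rel_entr(qm, pm).sum()) if symmetrize else forward
    return SimilarityResult(
        "kld",
        max(value, 0.0),
        {"pseudocount": pseudocount, "symmetrize": symmetrize},
        dp.samples.shape[0],
        dq.samples.shape[0],
    )


# ---------------------------------------------------------------------------
# Dispatch


def compare(p, q, measure: str, metric: MetricSpec = EUCLIDEAN, **params) -> SimilarityResult:
    """Run one measure by its Table-1 abbreviation (case-insensitive).

    Trajectory-pair measures accept Trajectories or (n, 3) arrays; ``wd`` and
    ``kld`` also accept prebuilt DimensionDistributions; ``ddm`` requires two
    StructureEnsembles and reports the mean per-site value as its scalar.
    """
    name = measure.lower()
    if name == "hd":
        return hausdorff(p, q, metric)
    if name == "dfd":
        return discrete_frechet(p, q, metric, **params)
    if name == "dwfd":
        return weak_frechet(p, q, metric)
    if name == "dtw":
        return dtw(p, q, metric, **params)
    if name == "lcss":
        return lcss(p, q, metric=metric, **params)
    if name == "wd":
        return wasserstein(p, q, **params)
    if name == "kld":
        return kld(p, q, **params)
    if name == "ddm":
        res = ddm(p, q, **params)
        return SimilarityResult(
            "ddm", res.value, dict(params), p.n_sites, q.n_sites
        )
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURE_NAMES}")
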