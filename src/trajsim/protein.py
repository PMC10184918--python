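"""Per-residue conformational-difference profiles for structure ensembles.

Two simulation ensembles of the same protein are superposed onto a common
reference frame, each residue's Cα path is treated as a trajectory, and any
similarity measure is evaluated residue-by-residue against its counterpart in
the other ensemble.  Peaks in the resulting profile localize conformational
differences; RMSF profiles quantify within-ensemble flexibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .geometry import EUCLIDEAN, MetricSpec
from .measures import MEASURE_NAMES, compare, ddm
from .trajectory import StructureEnsemble, Trajectory, superpose_ensemble

__all__ = [
    "ResidueProfile",
    "residue_trajectories",
    "superpose_pair",
    "profile",
    "lcss_epsilon_sweep",
    "rmsf",
]


@dataclass
class ResidueProfile:
    """One similarity value per residue for a pair of ensembles."""

    measure: str
    values: np.ndarray
    site_labels: Sequence
    params: dict = field(default_factory=dict)
    raw_values: np.ndarray | None = None  # LCSS raw match counts

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.site_labels):
            raise ValueError("values must be one per site label")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"residue_label": list(self.site_labels), "value": self.values})
        if self.raw_values is not None:
            df["raw"] = self.raw_values
        return df

    def argmax_label(self):
        return self.site_labels[int(np.argmax(self.values))]


def residue_trajectories(ensemble: StructureEnsemble) -> list[Trajectory]:
    """One trajectory per residue: the site's location at every frame, in frame order."""
    return ensemble.site_trajectories()


def superpose_pair(
    a: StructureEnsemble, b: StructureEnsemble, reference_frame: int = 0
) -> tuple[StructureEnsemble, StructureEnsemble]:
    """Superpose both ensembles onto one frame of ``a`` (all-site Kabsch fit).

    Using a single shared reference removes the arbitrary rigid offset
    between the two simulations, which would otherwise dominate every
    measure.
    """
    ref = a.coords[reference_frame]
    return superpose_ensemble(a, ref), superpose_ensemble(b, ref)


def _check_pair(a: StructureEnsemble, b: StructureEnsemble) -> None:
    if a.n_sites != b.n_sites:
        raise ValueError(f"site count mismatch: {a.n_sites} vs {b.n_sites}")


def profile(
    a: StructureEnsemble,
    b: StructureEnsemble,
    measure: str,
    params: dict | None = None,
    metric: MetricSpec = EUCLIDEAN,
    superpose: bool = True,
    reference_frame: int = 0,
    workers: int = 1,
) -> ResidueProfile:
    """Per-residue similarity profile between two ensembles.

    ``values[r]`` is the measure applied to residue r's trajectory in ``a``
    versus its counterpart in ``b``.  Both ensembles are first superposed
    onto frame ``reference_frame`` of ``a`` (skipped for DDM, whose
    intra-structure distances are rigid-motion invariant).  Residues are
    independent, so the computation parallelizes with worker-count-
    independent results.
    """
    name = measure.lower()
    if name not in MEASURE_NAMES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURE_NAMES}")
    _check_pair(a, b)
    params = dict(params or {})

    if name == "ddm":
        res = ddm(a, b, **params)
        return ResidueProfile("ddm", res.per_site, list(a.site_labels), params)

    if superpose:
        a, b = superpose_pair(a, b, reference_frame)
    ta, tb = a.site_trajectories(), b.site_trajectories()

    def one(r: int):
        res = compare(ta[r], tb[r], name, metric=metric, **params)
        return res.value, res.raw

    if workers > 1:
        results = Parallel(n_jobs=workers)(delayed(one)(r) for r in range(a.n_sites))
    else:
        results = [one(r) for r in range(a.n_sites)]
    values = np.array([v for v, _ in results])
    raws = None
    if name == "lcss":
        raws = np.array([raw for _, raw in results], dtype=float)
    return ResidueProfile(name, values, list(a.site_labels), params, raw_values=raws)


def lcss_epsilon_sweep(
    a: StructureEnsemble,
    b: StructureEnsemble,
    epsilons: Sequence[float],
    delta: float = math.inf,
    metric: MetricSpec = EUCLIDEAN,
    superpose: bool = True,
    workers: int = 1,
) -> list[ResidueProfile]:
    """LCSS profiles across a list of spatial thresholds ε (shared residue axis).

    Raw match counts are non-decreasing in ε at every residue, making the
    threshold sensitivity of LCSS explicit.
    """
    if len(epsilons) == 0:
        raise ValueError("epsilons must be non-empty")
    if any(e <= 0 for e in epsilons):
        raise ValueError("all epsilons must be > 0")
    if superpose:
        a, b = superpose_pair(a, b)
    return [
        profile(a, b, "lcss", {"epsilon": float(e), "delta": delta},
                metric=metric, superpose=False, workers=workers)
        for e in epsilons
    ]


def rmsf(ensemble: StructureEnsemble) -> np.ndarray:
    """Root-mean-square fluctuation of each site about its time-averaged position.

    rmsf_r = sqrt( mean_t ‖x_r(t) − mean_t x_r‖² ).  Superpose the ensemble
    first if frames carry arbitrary rigid motions.
    """
    if ensemble.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    mean = ensemble.coords.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(np.sum((ensemble.coords - mean) ** 2, axis=2), axis=0))
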