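"""Noise-aware similarity comparison of geolocator migration tracks.

Light-level geolocators yield roughly two noisy location fixes per day.  The
pipeline: average the daily fixes to one point per day, model each tracked
individual as per-day normal distributions (mean location + standard errors),
sample many plausible tracks per individual, and compare similarity-value
distributions *between* individuals against the *within*-individual ("noise")
distributions that resampling the same bird produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import EARTH_RADIUS_KM, EUCLIDEAN, MetricSpec
from .measures import MEASURE_NAMES, compare
from .trajectory import Trajectory, geographic_to_cartesian

__all__ = [
    "GAMMA_LEVEL",
    "TrackModel",
    "PairDesign",
    "SimilarityDistribution",
    "TrackSimilarity",
    "read_track_table",
    "write_track_table",
    "daily_average",
    "sample_tracks",
    "pair_design",
    "similarity_distributions",
    "scale_by_max",
    "lcss_threshold_sweep_tracks",
]

#: Reference level marking "half as dissimilar as the most dissimilar pair"
#: after max-scaling a measure's pairwise values.
GAMMA_LEVEL = 0.5

_DEG_PER_KM = 180.0 / (math.pi * EARTH_RADIUS_KM)  # ≈ 1/111.2 at the surface


@dataclass
class TrackModel:
    """Per-day sampling distribution of one tracked individual.

    ``mean_locs`` holds per-day (lon°, lat°) means; ``sds`` per-day
    (lon_sd, lat_sd) normal standard deviations, in ``sd_units`` ("km" or
    "deg").
    """

    individual_id: str
    days: np.ndarray
    mean_locs: np.ndarray
    sds: np.ndarray
    sd_units: str = "km"

    def __post_init__(self) -> None:
        ml = np.asarray(self.mean_locs, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        days = np.asarray(self.days)
        if ml.ndim != 2 or ml.shape[1] != 2:
            raise ValueError("mean_locs must be (D, 2) lon/lat degrees")
        if ml.shape[0] < 2:
            raise ValueError("a track model needs at least 2 days")
        if sd.shape != ml.shape:
            raise ValueError("sds must match mean_locs shape")
        if len(days) != ml.shape[0]:
            raise ValueError("days must match mean_locs length")
        if np.any(sd < 0):
            raise ValueError("standard deviations must be >= 0")
        if self.sd_units not in ("km", "deg"):
            raise ValueError("sd_units must be 'km' or 'deg'")
        object.__setattr__(self, "mean_locs", ml)
        object.__setattr__(self, "sds", sd)
        object.__setattr__(self, "days", days)

    @property
    def n_days(self) -> int:
        return self.mean_locs.shape[0]

    def sds_degrees(self) -> np.ndarray:
        """Per-day standard deviations converted to degrees (lon scaled by 1/cos φ)."""
        if self.sd_units == "deg":
            return self.sds.copy()
        lat = np.radians(self.mean_locs[:, 1])
        coslat = np.clip(np.abs(np.cos(lat)), 1e-6, None)
        out = np.empty_like(self.sds)
        out[:, 0] = self.sds[:, 0] * _DEG_PER_KM / coslat
        out[:, 1] = self.sds[:, 1] * _DEG_PER_KM
        return out


def read_track_table(path, sd_units: str = "km", individual_id: str | None = None) -> TrackModel:
    """Read a track CSV: columns date, lon, lat and optional lon_sd, lat_sd."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("date", "lon", "lat"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    sds = np.zeros((len(df), 2))
    if "lon_sd" in cols and "lat_sd" in cols:
        sds = np.column_stack([df[cols["lon_sd"]], df[cols["lat_sd"]]])
    name = individual_id
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return TrackModel(
        name,
        days=pd.to_datetime(df[cols["date"]]).to_numpy(),
        mean_locs=np.column_stack([df[cols["lon"]], df[cols["lat"]]]),
        sds=sds,
        sd_units=sd_units,
    )


def write_track_table(model: TrackModel, path) -> None:
    pd.DataFrame(
        {
            "date": model.days,
            "lon": model.mean_locs[:, 0],
            "lat": model.mean_locs[:, 1],
            "lon_sd": model.sds[:, 0],
            "lat_sd": model.sds[:, 1],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def _circular_mean_lon(lons: np.ndarray) -> float:
    rad = np.radians(np.asarray(lons, dtype=float))
    mean = math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return mean


def daily_average(fixes: Mapping) -> tuple[list, np.ndarray]:
    """Average the (1 or 2) daily fixes to one location per day.

    ``fixes`` maps date -> sequence of (lon°, lat°) fixes.  Longitudes are
    averaged circularly (±360-aware), so fixes straddling the antimeridian
    average to ±180, not 0.  Returns (sorted days, (D, 2) mean locations).
    """
    days = sorted(fixes)
    locs = np.empty((len(days), 2))
    for k, day in enumerate(days):
        pts = np.atleast_2d(np.asarray(fixes[day], dtype=float))
        if pts.size == 0:
            raise ValueError(f"day {day} has no location fix")
        locs[k, 0] = _circular_mean_lon(pts[:, 0])
        locs[k, 1] = float(np.mean(pts[:, 1]))
    return days, locs


def sample_tracks(
    model: TrackModel,
    n_samples: int,
    seed: int | np.random.SeedSequence = 0,
    radius: float = EARTH_RADIUS_KM,
) -> list[Trajectory]:
    """Draw noisy realizations of a track from its per-day normal distributions.

    Per sample and day: lon ~ N(mean_lon, lon_sd) (wrapped mod 360),
    lat ~ N(mean_lat, lat_sd) clipped to [−90, 90]; independent across days
    and samples; embedded on the sphere (km) so Euclidean measures apply.
    Reproducible from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    sds = model.sds_degrees()
    d = model.n_days
    noise = rng.standard_normal((n_samples, d, 2)) * sds[None, :, :]
    lonlat = model.mean_locs[None, :, :] + noise
    lonlat[:, :, 0] = (lonlat[:, :, 0] + 180.0) % 360.0 - 180.0
    lonlat[:, :, 1] = np.clip(lonlat[:, :, 1], -90.0, 90.0)
    times = np.arange(d, dtype=float)
    return [
        geographic_to_cartesian(lonlat[s], radius, times=times,
                                label=f"{model.individual_id}#{s}")
        for s in range(n_samples)
    ]


@dataclass(frozen=True)
class PairDesign:
    """Comparison plan for a cohort of K individuals and n samples each.

    Between individuals: every unordered pair of individuals, sample s of one
    against sample s of the other — K(K−1)/2 · n comparisons.  Within an
    individual: n disjoint random pairs from its own 2n samples — K · n
    comparisons.
    """

    individual_ids: tuple
    n_samples: int

    def __post_init__(self) -> None:
        if len(self.individual_ids) < 2:
            raise ValueError("need at least 2 individuals")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def between_pairs(self) -> list[tuple]:
        return list(combinations(self.individual_ids, 2))

    @property
    def n_between_pairs(self) -> int:
        k = len(self.individual_ids)
        return k * (k - 1) // 2

    @property
    def n_between(self) -> int:
        return self.n_between_pairs * self.n_samples

    @property
    def n_within(self) -> int:
        return len(self.individual_ids) * self.n_samples

    @property
    def samples_per_individual(self) -> int:
        """2n samples: n for between-comparisons, all 2n for disjoint within-pairs."""
        return 2 * self.n_samples

    def between_sample_pairs(self) -> list[tuple[int, int]]:
        return [(s, s) for s in range(self.n_samples)]

    def within_sample_pairs(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        perm = rng.permutation(self.samples_per_individual)
        return [(int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(self.n_samples)]


def pair_design(individual_ids: Sequence, n_samples: int) -> PairDesign:
    """Build the all-pairs comparison plan for a cohort."""
    return PairDesign(tuple(individual_ids), int(n_samples))


@dataclass
class SimilarityDistribution:
    """Histogrammed similarity values for one pair (between) or individual (within)."""

    kind: str  # "within" | "between"
    individual_pair: tuple
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    density: bool = False


@dataclass
class TrackSimilarity:
    """All planned comparisons for one measure on one cohort."""

    measure: str
    params: dict
    design: PairDesign
    between: dict = field(default_factory=dict)  # (idA, idB) -> values
    within: dict = field(default_factory=dict)  # id -> values
    raw_between: dict | None = None  # LCSS raw counts
    raw_within: dict | None = None

    def all_between(self) -> np.ndarray:
        return np.concatenate(list(self.between.values()))

    def all_within(self) -> np.ndarray:
        return np.concatenate(list(self.within.values()))

    def histograms(self, bins: int = 50, normalize_within: bool = True
                   ) -> list[SimilarityDistribution]:
        """Per-pair and per-individual histograms on shared bin edges.

        Within ("noise") histograms are density-normalized by default to make
        them magnitude-comparable with the between-individual histograms.
        """
        everything = np.concatenate([self.all_between(), self.all_within()])
        lo, hi = float(everything.min()), float(everything.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
        out = []
        for pair, vals in self.between.items():
            counts, _ = np.histogram(vals, bins=edges)
            out.append(SimilarityDistribution("between", pair, vals, edges,
                                              counts.astype(float)))
        for ind, vals in self.within.items():
            counts, _ = np.histogram(vals, bins=edges,
                                     density=normalize_within)
            out.append(
                SimilarityDistribution("within", (ind, ind), vals, edges,
                                       counts.astype(float), density=normalize_within)
            )
        return out


def _sample_cohort(
    models: Sequence[TrackModel], design: PairDesign, seed: int, radius: float
) -> tuple[dict, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(models) + 1)
    samples = {
        m.individual_id: sample_tracks(m, design.samples_per_individual, children[k], radius)
        for k, m in enumerate(models)
    }
    pairing_rng = np.random.default_rng(children[-1])
    return samples, pairing_rng


def _run_plan(
    samples: dict,
    design: PairDesign,
    pairing_rng: np.random.Generator,
    measure: str,
    params: dict,
    metric: MetricSpec,
) -> TrackSimilarity:
    name = measure.lower()
    if name not in MEASURE_NAMES or name == "ddm":
        raise ValueError(f"unsupported track measure {measure!r}")
    result = TrackSimilarity(name, dict(params), design)
    if name == "lcss":
        result.raw_between, result.raw_within = {}, {}

    def run_pairs(tr_a, tr_b, sample_pairs):
        vals = np.empty(len(sample_pairs))
        raws = np.empty(len(sample_pairs))
        for k, (sa, sb) in enumerate(sample_pairs):
            res = compare(tr_a[sa], tr_b[sb], name, metric=metric, **params)
            vals[k] = res.value
            raws[k] = res.raw if res.raw is not None else np.nan
        return vals, raws

    for a, b in design.between_pairs:
        vals, raws = run_pairs(samples[a], samples[b], design.between_sample_pairs())
        result.between[(a, b)] = vals
        if name == "lcss":
            result.raw_between[(a, b)] = raws
    for ind in design.individual_ids:
        pairs = design.within_sample_pairs(pairing_rng)
        vals, raws = run_pairs(samples[ind], samples[ind], pairs)
        result.within[ind] = vals
        if name == "lcss":
            result.raw_within[ind] = raws
    return result


def similarity_distributions(
    models: Sequence[TrackModel],
    measure: str,
    params: dict | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    design: PairDesign | None = None,
    metric: MetricSpec = EUCLIDEAN,
    radius: float = EARTH_RADIUS_KM,
) -> TrackSimilarity:
    """Execute the full comparison plan for one measure.

    Samples every individual's track model, runs all between-individual and
    within-individual comparisons of the design, and returns the value
    distributions (histogram helpers on the result).  Bit-reproducible from
    ``seed``.
    """
    if design is None:
        design = pair_design([m.individual_id for m in models], n_samples)
    samples, pairing_rng = _sample_cohort(models, design, seed, radius)
    return _run_plan(samples, design, pairing_rng, measure, dict(params or {}), metric)


def scale_by_max(values) -> tuple:
    """Scale a measure's pairwise values by their maximum (range becomes [0, 1]).

    Returns ``(scaled, GAMMA_LEVEL)``; the Γ level 0.5 marks pairs half as
    dissimilar as the most dissimilar pair.  Accepts a dict (pair -> value)
    or an array.
    """
    if isinstance(values, Mapping):
        arr = np.array(list(values.values()), dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to scale")
    top = arr.max()
    if top <= 0:
        raise ValueError("all values are zero; max-scaling is undefined")
    if isinstance(values, Mapping):
        return {k: float(v) / top for k, v in values.items()}, GAMMA_LEVEL
    return arr / top, GAMMA_LEVEL


def lcss_threshold_sweep_tracks(
    models: Sequence[TrackModel],
    epsilons_km: Sequence[float],
    delta: float = math.inf,
    n_samples: int = 1000,
    seed: int = 0,
    design: PairDesign | None = None,
    metric: MetricSpec = EUCLIDEAN,
    radius: float = EARTH_RADIUS_KM,
) -> dict[float, TrackSimilarity]:
    """LCSS distributions across several spatial thresholds ε (km).

    The same sampled tracks and within-pairings are reused for every ε, so
    raw match counts are non-decreasing in ε for every compared pair.
    """
    if len(epsilons_km) == 0:
        raise ValueError("epsilons_km must be non-empty")
    if any(e <= 0 for e in epsilons_km):
        raise ValueError("all epsilons must be > 0")
    if design is None:
        design = pair_design([m.individual_id for m in models], n_samples)
    out = {}
    for eps in epsilons_km:
        samples, pairing_rng = _sample_cohort(models, design, seed, radius)
        out[float(eps)] = _run_plan(
            samples, design, pairing_rng, "lcss",
            {"epsilon": float(eps), "delta": delta}, metric,
        )
    return out
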