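"""Synthetic generators with the statistical structure of the two case studies.

``gen_protein_pair`` emulates a pair of Cα simulation ensembles: every residue
vibrates as a tethered (mean-reverting) random walk about an anchor on a
protein-like chain, and one ensemble carries a localized conformational shift
— a contiguous residue block whose anchors are displaced.  ``gen_track_cohort``
emulates a cohort of migration-track models: individual mean routes scatter
around a shared continent-crossing base route (optionally with stopover
plateaus), and per-day location error enters as normal standard deviations,
the geolocator noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory import StructureEnsemble, write_structure_frames
from .tracks import TrackModel, write_track_table

__all__ = [
    "ProteinSynthSpec",
    "TrackSynthSpec",
    "gen_protein_pair",
    "gen_track_cohort",
    "write_protein_pair",
    "write_track_cohort",
]


@dataclass(frozen=True)
class ProteinSynthSpec:
    """Parameters of the synthetic conformational-ensemble pair.

    ``sigma`` is the per-frame tether noise (Å), ``theta`` the mean-reversion
    rate of the walk (theta = 1 gives i.i.d. Normal(anchor, sigma²) frames),
    ``shift_block`` the half-open residue index range whose anchors are
    displaced by ``shift_vector`` in the second ensemble.  Defaults follow
    the package's reference scenario: 100 residues, 200 frames, σ = 0.3 Å
    and a 5σ block shift.
    """

    n_sites: int = 100
    n_frames: int = 200
    sigma: float = 0.3
    theta: float = 0.5
    shift_block: tuple[int, int] = (40, 50)
    shift_vector: tuple[float, float, float] = (1.5, 0.0, 0.0)
    anchor_spacing: float = 3.8  # consecutive Cα–Cα distance, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_frames < 1:
            raise ValueError("n_sites and n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        lo, hi = self.shift_block
        if not (0 <= lo <= hi <= self.n_sites):
            raise ValueError("shift_block must lie within [0, n_sites)")


@dataclass(frozen=True)
class TrackSynthSpec:
    """Parameters of the synthetic migration cohort.

    ``route_spread_km`` scales the smooth per-individual deviation from the
    base route; ``noise_sd_km`` is the per-day location error (the model's
    normal standard deviation); ``stopover_days`` optionally inserts one
    stopover plateau of that length per individual.  Defaults follow the
    package's reference cohort: 8 individuals, 90 daily locations, 500 km
    between-individual spread, 50 km daily error.
    """

    n_individuals: int = 8
    n_days: int = 90
    route_spread_km: float = 500.0
    noise_sd_km: float = 50.0
    stopover_days: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_days < 2:
            raise ValueError("need >= 2 individuals and >= 2 days")
        if self.route_spread_km < 0 or self.noise_sd_km < 0:
            raise ValueError("scales must be >= 0")


def _anchor_chain(rng: np.random.Generator, n: int, spacing: float) -> np.ndarray:
    """Protein-like backbone: a persistent random walk with fixed step length."""
    anchors = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for k in range(1, n):
        direction = direction + 0.6 * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        anchors[k] = anchors[k - 1] + spacing * direction
    return anchors


def _tethered_walk(
    rng: np.random.Generator, anchors: np.ndarray, n_frames: int, theta: float, sigma: float
) -> np.ndarray:
    """x(t+1) = x(t) + θ·(anchor − x(t)) + N(0, σ²·I), started at stationarity.

    The stationary per-axis standard deviation is σ/√(θ(2−θ)); drawing the
    first frame from it avoids a burn-in transient (and, with θ = 1, makes
    every frame i.i.d. Normal(anchor, σ²)).
    """
    n = anchors.shape[0]
    out = np.empty((n_frames, n, 3))
    s0 = sigma / math.sqrt(theta * (2.0 - theta))
    x = anchors + s0 * rng.standard_normal((n, 3))
    out[0] = x
    for t in range(1, n_frames):
        x = x + theta * (anchors - x) + sigma * rng.standard_normal((n, 3))
        out[t] = x
    return out


def gen_protein_pair(spec: ProteinSynthSpec) -> tuple[StructureEnsemble, StructureEnsemble]:
    """Generate the (reference, shifted) synthetic ensemble pair.

    Both ensembles share the same anchor chain; ensemble B's anchors inside
    ``shift_block`` are displaced by ``shift_vector``.  Noise realizations
    are independent between the ensembles.  Pure function of the spec: the
    same seed yields bit-identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    s_anchor, s_a, s_b = root.spawn(3)
    anchors = _anchor_chain(np.random.default_rng(s_anchor), spec.n_sites, spec.anchor_spacing)
    anchors_b = anchors.copy()
    lo, hi = spec.shift_block
    anchors_b[lo:hi] += np.asarray(spec.shift_vector, dtype=float)
    labels = list(range(1, spec.n_sites + 1))
    a = StructureEnsemble(
        _tethered_walk(np.random.default_rng(s_a), anchors, spec.n_frames, spec.theta, spec.sigma),
        site_labels=labels,
        units="angstrom",
    )
    b = StructureEnsemble(
        _tethered_walk(np.random.default_rng(s_b), anchors_b, spec.n_frames, spec.theta, spec.sigma),
        site_labels=labels,
        units="angstrom",
    )
    return a, b


# Base route waypoints of the synthetic cohort, (unwrapped lon°, lat°): an
# Alaska → East Africa great-arc-like path crossing the antimeridian.
_BASE_WAYPOINTS = np.array(
    [
        [200.0, 65.0],  # 200°E ≡ −160° (Alaska)
        [150.0, 60.0],  # East Siberia
        [70.0, 45.0],  # Kazakhstan
        [50.0, 25.0],  # Arabia
        [40.0, 5.0],  # East Africa
    ]
)

_DEG_PER_KM = 180.0 / (np.pi * 6371.0)


def _base_route(n_days: int) -> np.ndarray:
    """Interpolate the waypoints to one (lon, lat) per day (lon still unwrapped)."""
    seg = np.linalg.norm(np.diff(_BASE_WAYPOINTS, axis=0), axis=1)
    u_way = np.concatenate([[0.0], np.cumsum(seg)]) / seg.sum()
    u = np.linspace(0.0, 1.0, n_days)
    lon = np.interp(u, u_way, _BASE_WAYPOINTS[:, 0])
    lat = np.interp(u, u_way, _BASE_WAYPOINTS[:, 1])
    return np.column_stack([lon, lat])


def _time_warp(rng: np.random.Generator, n_days: int, stopover_days: int) -> np.ndarray:
    """Progress parameter with one zero-speed (stopover) plateau per individual."""
    speed = np.ones(n_days - 1)
    start = int(rng.integers(n_days // 3, max(2 * n_days // 3, n_days // 3 + 1)))
    stop = min(start + stopover_days, n_days - 1)
    speed[start:stop] = 0.0
    u = np.concatenate([[0.0], np.cumsum(speed)])
    return u / u[-1]


def gen_track_cohort(spec: TrackSynthSpec) -> list[TrackModel]:
    """Generate K synthetic track models around the shared base route.

    Each individual's mean track is the base route plus a smooth random
    offset (vanishing at the endpoints — shared breeding and wintering
    grounds) scaled by ``route_spread_km``, optionally warped by a stopover
    plateau; its per-day sds equal ``noise_sd_km``.  Pure function of the
    spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    base = _base_route(spec.n_days)
    u = np.linspace(0.0, 1.0, spec.n_days)
    models = []
    for k in range(spec.n_individuals):
        if spec.stopover_days:
            uk = _time_warp(rng, spec.n_days, spec.stopover_days)
            lon = np.interp(uk, u, base[:, 0])
            lat = np.interp(uk, u, base[:, 1])
        else:
            lon, lat = base[:, 0].copy(), base[:, 1].copy()
        # smooth offset: two low-frequency modes per coordinate, zero at endpoints
        amp = rng.uniform(-1.0, 1.0, size=4)
        shape1, shape2 = np.sin(np.pi * u), np.sin(2 * np.pi * u)
        off_lon_km = spec.route_spread_km * (amp[0] * shape1 + 0.5 * amp[1] * shape2)
        off_lat_km = spec.route_spread_km * (amp[2] * shape1 + 0.5 * amp[3] * shape2)
        coslat = np.clip(np.abs(np.cos(np.radians(lat))), 1e-6, None)
        lon = lon + off_lon_km * _DEG_PER_KM / coslat
        lat = np.clip(lat + off_lat_km * _DEG_PER_KM, -90.0, 90.0)
        lon = (lon + 180.0) % 360.0 - 180.0
        days = np.datetime64("2021-08-01") + np.arange(spec.n_days)
        sds = np.full((spec.n_days, 2), spec.noise_sd_km)
        models.append(
            TrackModel(f"bird{k:02d}", days, np.column_stack([lon, lat]), sds, sd_units="km")
        )
    return models


def write_protein_pair(a: StructureEnsemble, b: StructureEnsemble, out_prefix: str) -> tuple[str, str]:
    """Write the ensemble pair as two multi-model PDB files."""
    pa, pb = f"{out_prefix}_a.pdb", f"{out_prefix}_b.pdb"
    write_structure_frames(a, pa)
    write_structure_frames(b, pb)
    return pa, pb


def write_track_cohort(models, out_dir) -> list[str]:
    """Write one track CSV per individual into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for m in models:
        p = os.path.join(str(out_dir), f"{m.individual_id}.csv")
        write_track_table(m, p)
        paths.append(p)
    return paths
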