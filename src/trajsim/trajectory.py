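"""Core trajectory containers and readers/writers.

A *trajectory* is an ordered sequence of 3-D locations (elements), optionally
timestamped.  A *structure ensemble* is an equal-length collection of such
trajectories, one per site (e.g. one per residue Cα), sharing a common time
axis.  Order-independent measures work on *dimension distributions*: the three
per-axis empirical distributions extracted from a trajectory.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import EARTH_RADIUS_KM, kabsch_superpose, apply_rigid, lonlat_to_xyz

__all__ = [
    "Trajectory",
    "StructureEnsemble",
    "DimensionDistributions",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_structure_frames",
    "write_structure_frames",
    "geographic_to_cartesian",
    "superpose_ensemble",
    "to_distributions",
    "pair_distributions",
]


@dataclass
class Trajectory:
    """Ordered sequence of 3-D locations with optional timestamps.

    Parameters
    ----------
    coords : (n, 3) array of finite floats, n >= 1.
    times : optional (n,) non-decreasing array of timestamps.
    label : free-text identifier.
    units : unit of the coordinates, carried as metadata only (never converted
        implicitly); e.g. ``"angstrom"``, ``"nm"``, ``"km"``.
    """

    coords: np.ndarray
    times: np.ndarray | None = None
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim == 1:
            c = c.reshape(1, -1)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got shape {c.shape}")
        if c.shape[0] < 1:
            raise ValueError("a trajectory needs at least one element")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", c)
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.shape != (c.shape[0],):
                raise ValueError("times must match the number of elements")
            if np.any(np.diff(t) < 0):
                raise ValueError("times must be non-decreasing")
            object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def reversed(self) -> "Trajectory":
        """Element order reversed (times dropped)."""
        return Trajectory(self.coords[::-1].copy(), None, self.label, self.units)

    def permuted(self, order: Sequence[int]) -> "Trajectory":
        """Reorder elements (drops times; used to probe order-(in)dependence)."""
        return Trajectory(self.coords[np.asarray(order)], None, self.label, self.units)


@dataclass
class StructureEnsemble:
    """T frames of R sites: one trajectory per site on a shared time axis.

    ``coords`` has shape (T, R, 3); ``site_labels`` identifies the R sites
    (residue numbers for proteins).
    """

    coords: np.ndarray
    site_labels: Sequence = field(default_factory=list)
    times: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"coords must be (T, R, 3), got shape {c.shape}")
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise ValueError("need at least one frame and one site")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", c)
        if not self.site_labels:
            object.__setattr__(self, "site_labels", list(range(c.shape[1])))
        elif len(self.site_labels) != c.shape[1]:
            raise ValueError("site_labels must match the number of sites")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.coords[t]

    def site_trajectories(self) -> list[Trajectory]:
        """One Trajectory per site, elements in frame order."""
        return [
            Trajectory(self.coords[:, r, :], self.times, label=str(self.site_labels[r]),
                       units=self.units)
            for r in range(self.n_sites)
        ]


@dataclass
class DimensionDistributions:
    """Per-axis empirical distributions of one trajectory.

    ``samples`` is the (n, 3) coordinate array; each column is the sample
    multiset of one spatial axis.  The optional binned form stores shared bin
    edges per axis (``bin_edges``: (3, bins+1)) and the probability mass per
    bin per axis (``masses``: (3, bins), each row summing to 1).
    """

    samples: np.ndarray
    bin_edges: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 1:
            raise ValueError("samples must be (n, 3) with n >= 1")
        object.__setattr__(self, "samples", s)
        if (self.bin_edges is None) != (self.masses is None):
            raise ValueError("bin_edges and masses must be given together")
        if self.masses is not None:
            m = np.asarray(self.masses, dtype=float)
            e = np.asarray(self.bin_edges, dtype=float)
            if m.shape[0] != 3 or e.shape != (3, m.shape[1] + 1):
                raise ValueError("binned form must be (3, bins) masses with (3, bins+1) edges")
            if np.any(m < 0):
                raise ValueError("bin masses must be non-negative")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("bin masses must sum to 1 per axis")
            object.__setattr__(self, "masses", m)
            object.__setattr__(self, "bin_edges", e)

    @property
    def samples_x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def samples_y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def samples_z(self) -> np.ndarray:
        return self.samples[:, 2]


# ---------------------------------------------------------------------------
# Delimited-table I/O


def _sniff(first_line: str) -> str | None:
    """Return the delimiter (',' or None for whitespace)."""
    return "," if "," in first_line else None


def read_trajectory_table(
    path,
    column_map: Mapping[str, int | str] | None = None,
    delimiter: str | None = None,
    label: str = "",
    units: str = "",
) -> Trajectory:
    """Read a trajectory from a delimited text table (one row per element).

    The table may be comma- or whitespace-delimited with an optional header
    row.  Default columns are ``t, x, y, z`` (by name when a header is
    present, else by position; a headerless 3-column file is read as
    ``x, y, z`` with no times).  ``column_map`` overrides the mapping, e.g.
    ``{"x": 1, "y": 2, "z": 3}`` (0-based positions) or header names.
    Rows are kept in file order — no implicit sorting by time.
    """
    with open(path, "r") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty trajectory table")
    sep = delimiter or _sniff(lines[0])
    first = lines[0].split(sep) if sep else lines[0].split()
    has_header = False
    for tok in first:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break

    if sep is None:  # normalize whitespace-delimited input for the C parser
        text = "\n".join(",".join(ln.split()) for ln in lines)
    df = pd.read_csv(
        io.StringIO(text),
        sep=",",
        header=0 if has_header else None,
        skip_blank_lines=True,
        float_precision="round_trip",
    )
    if not has_header:
        df.columns = list(range(df.shape[1]))

    def col(key, ref):
        if isinstance(ref, int):
            if ref >= df.shape[1]:
                raise ValueError(f"{path}: column {ref} for {key!r} out of range")
            return df.iloc[:, ref]
        if ref not in df.columns:
            raise ValueError(f"{path}: no column named {ref!r} for {key!r}")
        return df[ref]

    if column_map is None:
        if has_header:
            names = [str(c).strip().lower() for c in df.columns]
            df.columns = names
            if not {"x", "y", "z"}.issubset(names):
                raise ValueError(f"{path}: header must provide x, y, z columns")
            column_map = {"x": "x", "y": "y", "z": "z"}
            if "t" in names:
                column_map["t"] = "t"
        else:
            if df.shape[1] < 3:
                raise ValueError(f"{path}: need at least 3 coordinate columns for 3-D data")
            if df.shape[1] == 3:
                column_map = {"x": 0, "y": 1, "z": 2}
            else:
                column_map = {"t": 0, "x": 1, "y": 2, "z": 3}
    missing = {"x", "y", "z"} - set(column_map)
    if missing:
        raise ValueError(f"{path}: column_map lacks coordinate columns {sorted(missing)}")

    parsed = {}
    header_offset = 2 if has_header else 1  # 1-based line number of the first data row
    for key, ref in column_map.items():
        series = pd.to_numeric(col(key, ref), errors="coerce")
        bad = series.index[~np.isfinite(series.to_numpy(dtype=float))]
        if len(bad):
            raise ValueError(
                f"{path}: malformed value in column {ref!r} at line {int(bad[0]) + header_offset}"
            )
        parsed[key] = series.to_numpy(dtype=float)

    coords = np.column_stack([parsed["x"], parsed["y"], parsed["z"]])
    times = parsed.get("t")
    return Trajectory(coords, times, label=label or str(path), units=units)


def write_trajectory_table(traj: Trajectory, path, delimiter: str = ",", header: bool = True) -> None:
    """Write a trajectory as delimited text; round-trips coordinates exactly."""
    cols = {}
    if traj.times is not None:
        cols["t"] = traj.times
    cols.update(x=traj.coords[:, 0], y=traj.coords[:, 1], z=traj.coords[:, 2])
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False, header=header,
                              float_format="%.17g")


# ---------------------------------------------------------------------------
# Structures (multi-model PDB)


def read_structure_frames(path, selection: str = "name CA") -> StructureEnsemble:
    """Read a multi-model PDB into a StructureEnsemble (one site per residue).

    The default selection keeps one Cα per residue, the residue's reference
    position.  Coordinates are returned in Å.  Every protein residue must
    contain exactly one selected atom; frames are the PDB MODELs.
    """
    import mdtraj as md

    traj = md.load(str(path))
    top = traj.topology
    idx = top.select(selection)
    if len(idx) == 0:
        raise ValueError(f"{path}: selection {selection!r} matches no atom")
    selected = set(int(i) for i in idx)
    labels = []
    ordered = []
    for res in top.residues:
        hits = [a.index for a in res.atoms if a.index in selected]
        if not hits:
            if res.is_protein:
                raise ValueError(
                    f"{path}: residue {res.name}{res.resSeq} lacks an atom matching {selection!r}"
                )
            continue
        ordered.extend(sorted(hits))
        labels.extend([res.resSeq] * len(hits))
    coords = traj.xyz[:, ordered, :] * 10.0  # mdtraj stores nm; PDB convention is Å
    times = None
    if traj.time is not None and len(traj.time) == coords.shape[0]:
        times = np.asarray(traj.time, dtype=float)
    return StructureEnsemble(coords, site_labels=labels, times=times, units="angstrom")


def write_structure_frames(ensemble: StructureEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (one Cα pseudo-atom per site, Å).

    Fixed-column ATOM records per the PDB 3.3 layout, MODEL/ENDMDL framing;
    readable by any standard structure reader.
    """
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"MODEL     {t + 1:4d}\n")
            for r in range(ensemble.n_sites):
                x, y, z = ensemble.coords[t, r]
                label = ensemble.site_labels[r]
                try:
                    resseq = int(label)
                except (TypeError, ValueError):
                    resseq = r + 1
                serial = (r + 1) % 100000
                fh.write(
                    f"ATOM  {serial:5d}  CA  ALA A{resseq % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {'C':>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def geographic_to_cartesian(
    track: np.ndarray, radius: float = EARTH_RADIUS_KM, times: np.ndarray | None = None,
    label: str = "",
) -> Trajectory:
    """Embed a (lon°, lat°) track on a sphere of the given radius (km).

    Chord distances between embedded points approximate great-circle
    distances for nearby points, so the standard 3-D measures apply
    unchanged to geographic tracks.
    """
    return Trajectory(lonlat_to_xyz(track, radius), times=times, label=label, units="km")


def superpose_ensemble(
    ensemble: StructureEnsemble, reference: int | np.ndarray = 0
) -> StructureEnsemble:
    """Rigidly fit every frame onto a reference frame using all sites.

    ``reference`` is either a frame index into the ensemble or an explicit
    (R, 3) coordinate array (e.g. a frame of another ensemble, so two
    ensembles can share one reference).  Single-frame ensembles with an
    integer reference are returned unchanged.
    """
    if isinstance(reference, (int, np.integer)):
        if not (0 <= reference < ensemble.n_frames):
            raise IndexError(f"reference frame {reference} out of range")
        if ensemble.n_frames == 1:
            return ensemble
        ref = ensemble.coords[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (ensemble.n_sites, 3):
            raise ValueError("reference coordinates must be (R, 3)")
    out = np.empty_like(ensemble.coords)
    for t in range(ensemble.n_frames):
        rot, trans, _ = kabsch_superpose(ensemble.coords[t], ref)
        out[t] = apply_rigid(ensemble.coords[t], rot, trans)
    return replace(ensemble, coords=out)


# ---------------------------------------------------------------------------
# Trajectory -> per-axis distributions


def _axis_edges(lo: float, hi: float, bins: int) -> np.ndarray:
    if lo == hi:  # degenerate range: widen like numpy.histogram does
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, bins + 1)


def to_distributions(
    traj: Trajectory | np.ndarray,
    bins: int = 100,
    joint_range: Sequence[tuple[float, float]] | None = None,
) -> DimensionDistributions:
    """Reduce a trajectory to its three per-axis empirical distributions.

    Bins are closed-left/open-right with the final bin closed (numpy
    convention).  ``joint_range`` fixes the per-axis (min, max) support —
    pass the union of two trajectories' ranges to put both on shared edges.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    coords = traj.coords if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    edges = np.empty((3, bins + 1))
    masses = np.empty((3, bins))
    for ax in range(3):
        if joint_range is not None:
            lo, hi = joint_range[ax]
        else:
            lo, hi = coords[:, ax].min(), coords[:, ax].max()
        edges[ax] = _axis_edges(float(lo), float(hi), bins)
        counts, _ = np.histogram(coords[:, ax], bins=edges[ax])
        masses[ax] = counts / counts.sum()
    return DimensionDistributions(coords, bin_edges=edges, masses=masses)


def pair_distributions(
    p: Trajectory | np.ndarray, q: Trajectory | np.ndarray, bins: int = 100
) -> tuple[DimensionDistributions, DimensionDistributions]:
    """Distributions for two trajectories on shared per-axis bin edges.

    The edges span the union of both trajectories' per-axis ranges, so the
    two binned distributions live on identical support (required by the
    Kullback–Leibler divergence).
    """
    cp = p.coords if isinstance(p, Trajectory) else np.asarray(p, dtype=float)
    cq = q.coords if isinstance(q, Trajectory) else np.asarray(q, dtype=float)
    rng = [
        (min(cp[:, ax].min(), cq[:, ax].min()), max(cp[:, ax].max(), cq[:, ax].max()))
        for ax in range(3)
    ]
    return to_distributions(cp, bins, rng), to_distributions(cq, bins, rng)
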