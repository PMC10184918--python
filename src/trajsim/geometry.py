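"""Distance metrics, geographic embedding, and rigid-body (Kabsch) superposition.

Every similarity measure consumes pairwise element distances through a
:class:`MetricSpec`, so the same dynamic programs run unchanged on protein
coordinates (nm/Å, Euclidean) and on migration tracks (km, chord-on-sphere or
great-circle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

EARTH_RADIUS_KM = 6371.0

_METRIC_NAMES = ("euclidean3d", "haversine")


@dataclass(frozen=True)
class MetricSpec:
    """How to measure the distance between two trajectory elements.

    ``euclidean3d`` treats elements as points in 3-D space (the native
    convention of all measures).  ``haversine`` treats the first two
    coordinates of each element as (longitude°, latitude°) and returns
    great-circle distances in km on a sphere of radius ``earth_radius``.
    """

    name: str = "euclidean3d"
    earth_radius: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.name not in _METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; choose from {_METRIC_NAMES}")
        if self.earth_radius <= 0:
            raise ValueError("earth_radius must be positive")

    def pairwise(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """All-pairs distance matrix between element arrays ``a`` (n,3) and ``b`` (m,3)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if self.name == "euclidean3d":
            return cdist(a, b)
        return haversine_km(a[:, None, :2], b[None, :, :2], self.earth_radius)

    def distance(self, p: np.ndarray, q: np.ndarray) -> float:
        return float(self.pairwise(np.atleast_2d(p), np.atleast_2d(q))[0, 0])


EUCLIDEAN = MetricSpec("euclidean3d")


def haversine_km(a, b, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Great-circle distance between (lon°, lat°) arrays, broadcast like numpy."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def lonlat_to_xyz(lonlat: np.ndarray, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Embed (lon°, lat°) points on a sphere of the given radius.

    x = R·cosφ·cosλ, y = R·cosφ·sinλ, z = R·sinφ.  Chord distances between the
    images approximate great-circle distances for nearby points.
    """
    lonlat = np.atleast_2d(np.asarray(lonlat, dtype=float))
    lon, lat = lonlat[:, 0], lonlat[:, 1]
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(lon < -180.0) or np.any(lon >= 360.0):
        raise ValueError("longitude out of range [-180, 360)")
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        (
            radius * np.cos(phi) * np.cos(lam),
            radius * np.cos(phi) * np.sin(lam),
            radius * np.sin(phi),
        )
    )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference`` (both R×3, R ≥ 3).

    Returns ``(rotation, translation, rmsd)`` where applying
    ``x @ rotation.T + translation`` to the mobile frame minimizes the
    root-mean-square deviation over all proper rigid motions.  The rotation is
    always proper (det = +1): if the best orthogonal transform is a reflection,
    the singular direction with the smallest singular value is flipped.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"site count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected R x 3 coordinate arrays")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 sites for a unique superposition")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a rigid motion returned by :func:`kabsch_superpose` to an (n,3) array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)
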