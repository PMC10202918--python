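"""Small helpers for directions on the unit sphere.

Conventions used throughout the package: latitude = arcsin(z) in
[-pi/2, pi/2], longitude = atan2(y, x) in [-pi, pi].  Longitude 0 is the
anterior midline, the occipital pole sits at longitude +/-pi, and the left
hemisphere occupies negative longitudes (the left half-plane after
projection).
"""

from __future__ import annotations

import numpy as np


def unit_vector(lat_rad: float, lon_rad: float) -> np.ndarray:
    """Unit 3-vector for a (latitude, longitude) pair in radians."""
    cl = np.cos(lat_rad)
    return np.array(
        [cl * np.cos(lon_rad), cl * np.sin(lon_rad), np.sin(lat_rad)]
    )


def latlon(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latitude/longitude arrays (radians) for an (n, 3) unit-vector array."""
    coords = np.atleast_2d(coords)
    lat = np.arcsin(np.clip(coords[:, 2], -1.0, 1.0))
    lon = np.arctan2(coords[:, 1], coords[:, 0])
    return lat, lon


def angular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance (radians) between unit vectors, broadcasting."""
    dots = np.clip(a @ np.swapaxes(np.atleast_2d(b), -1, -2), -1.0, 1.0)
    return np.arccos(dots)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform (n, 3) point set on the unit sphere (Fibonacci lattice)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    lon = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(lon), r * np.sin(lon), z])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
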