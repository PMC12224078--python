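"""Low-level vector geometry: dihedrals and internal-coordinate atom placement.

All angles are in degrees, dihedrals follow the IUPAC sign convention
(looking from atom b to atom c, the far bond rotated clockwise gives a
positive angle) and are reported in (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "angle", "place_atom", "wrap_angle"]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float), 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # -180 is mapped to +180 so the interval is half-open at the bottom
    wrapped = np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    theta: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d such that |cd| = bond, angle(b,c,d) = theta and
    dihedral(a,b,c,d) = torsion (NeRF construction).

    Parameters are in Å and degrees.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta_r = np.radians(theta)
    chi_r = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise ValueError("cannot place atom: reference atoms are collinear")
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta_r),
            bond * np.sin(theta_r) * np.cos(chi_r),
            bond * np.sin(theta_r) * np.sin(chi_r),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local
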