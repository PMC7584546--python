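"""Small 3D geometry helpers (distances, angles, torsions, frames)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "angle_deg",
    "dihedral_deg",
    "wrap_deg",
    "rotation_about_axis",
    "lsq_plane",
    "orthonormal_to",
]


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion p0-p1-p2-p3, degrees in (-180, 180] (IUPAC sign convention)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise ValueError("dihedral undefined: coincident axis points")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return wrap_deg(ang)


def wrap_deg(x: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    y = (float(x) + 180.0) % 360.0 - 180.0
    return 180.0 if y == -180.0 else y


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("zero rotation axis")
    k = axis / n
    th = np.radians(angle_deg_)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def lsq_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal)."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[-1]


def orthonormal_to(v: np.ndarray) -> np.ndarray:
    """A unit vector orthogonal to v."""
    v = np.asarray(v, float)
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 * np.linalg.norm(v) else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, ref)
    return u / np.linalg.norm(u)


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |d-c| = bond, angle(b,c,d) = angle (deg)
    and torsion(a,b,c,d) = torsion (deg)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    th = np.radians(angle)
    ph = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
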