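"""Small geometry kernel: torsions, internal-coordinate atom placement, rotations.

All coordinates are ndarray of shape (3,) or (n, 3), units Å, angles in degrees
unless a function name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "rotation_about_axis",
    "rotation_between",
    "rigid_transform",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    u = _unit(np.asarray(a, float) - b)
    w = _unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # np.arctan2 returns (-180, 180]; -180 maps to +180 for determinism
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    u = _unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit direction v_from onto v_to."""
    a = _unit(np.asarray(v_from, float))
    b = _unit(np.asarray(v_to, float))
    cross = np.cross(a, b)
    dot = float(np.dot(a, b))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # opposite directions: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    axis = cross / np.linalg.norm(cross)
    angle = np.degrees(np.arctan2(np.linalg.norm(cross), dot))
    return rotation_about_axis(axis, angle)


def rigid_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t row-wise."""
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + np.asarray(translation, float)
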