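"""Internal-coordinate geometry helpers: angles, dihedrals, NeRF placement."""

from __future__ import annotations

import numpy as np


def bond_length(a, b) -> float:
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -np.degrees(np.arctan2(y, x))  # IUPAC sign convention
    return float(ang if ang != -180.0 else 180.0)


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given predecessors a-b-c and internal coordinates.

    ``bond`` is |c-d| in Å, ``angle_deg`` the b-c-d angle, ``torsion_deg`` the
    a-b-c-d torsion.  This is the standard natural-extension reference frame
    construction used to grow a polymer from internal coordinates.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (through 0)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rotate_about_line(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate ``points`` about the line through ``origin`` along ``axis``."""
    R = rotation_about_axis(axis, angle_deg)
    origin = np.asarray(origin, float)
    return (np.atleast_2d(points) - origin) @ R.T + origin


def wrap_angle(deg):
    """Wrap angle(s) to (-180, 180]."""
    out = (np.asarray(deg, float) + 180.0) % 360.0 - 180.0
    return out + 360.0 * (out == -180.0) * 0  # keep -180 -> 180 handled below


def angular_diff(a, b):
    """Smallest signed difference a-b in degrees, in [-180, 180)."""
    return (np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0
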