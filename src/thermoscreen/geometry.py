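"""Small geometry primitives shared across the toolkit.

All angles are in degrees, all lengths in Å. `place_atom` is the exact
inverse of (`pairwise_distance`, `angle`, `dihedral`): an atom placed with
given internal coordinates reproduces them to machine precision, which the
internal-coordinate builders in the disulfide scanner rely on.
"""

from __future__ import annotations

import numpy as np


def pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0–p1–p2 in degrees, in [0, 180]."""
    v0 = np.asarray(p0, float) - p1
    v1 = np.asarray(p2, float) - p1
    c = np.dot(v0, v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0–p1–p2–p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a–b–c.

    The returned point satisfies |D − c| = ``bond``,
    angle(b, c, D) = ``bond_angle`` and dihedral(a, b, c, D) = ``torsion``
    (NeRF construction).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.deg2rad(bond_angle)
    dih = np.deg2rad(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("reference atoms a, b, c are collinear")
    n = n / nn
    m = np.cross(n, bc)
    d = bond * np.array(
        [
            -np.cos(ang),
            -np.sin(ang) * np.cos(dih),
            -np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def wrap_angle(x):
    """Wrap angle(s) in degrees to (-180, 180]."""
    return -((-np.asarray(x, float) + 180.0) % 360.0 - 180.0)
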