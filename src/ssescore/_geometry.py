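"""Low-level rigid-body geometry: superposition, dihedrals, segment distances.

All angles are in degrees, all lengths in Angstrom.  Batch variants operate on
``(n, 3)`` stacks and are used by the packing machinery to keep per-model
scoring cost low.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "unit",
    "kabsch",
    "dihedral",
    "dihedral_batch",
    "rotation_about_axis",
    "random_rotation",
    "segment_closest_points",
    "segment_closest_points_batch",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit length."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of point set ``P`` onto ``Q``.

    Returns ``(R, t)`` such that ``P @ R.T + t`` minimizes the RMSD to ``Q``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points in degrees, in (-180, 180]."""
    return float(
        dihedral_batch(
            np.asarray(p0)[None], np.asarray(p1)[None],
            np.asarray(p2)[None], np.asarray(p3)[None],
        )[0]
    )


def dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized signed dihedral (degrees) for stacks of four points.

    Sign follows the usual convention: looking along ``p1 -> p2``, a positive
    angle is a right-handed rotation from the ``p0`` side onto the ``p3`` side.
    Degenerate configurations (collinear points) return 0.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    n1 = np.where(n1 < 1e-12, 1.0, n1)
    b1u = b1 / n1
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)
    return ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    return Rotation.from_rotvec(np.radians(angle_deg) * unit(np.asarray(axis, float))).as_matrix()


def random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    """Random rotation about a uniformly random axis, angle <= ``max_angle_deg``."""
    v = rng.normal(size=3)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    return rotation_about_axis(v, angle)


def segment_closest_points(a0, a1, b0, b1):
    """Closest points between two 3D line segments.

    Returns ``(pa, pb, distance)`` with ``pa`` on segment A and ``pb`` on B.
    Raises ``ValueError`` for zero-length segments.
    """
    a0 = np.asarray(a0, float)
    a1 = np.asarray(a1, float)
    b0 = np.asarray(b0, float)
    b1 = np.asarray(b1, float)
    if np.linalg.norm(a1 - a0) < 1e-12 or np.linalg.norm(b1 - b0) < 1e-12:
        raise ValueError("zero-length segment")
    pa, pb, dist = segment_closest_points_batch(a0[None], a1[None], b0[None], b1[None])
    return pa[0], pb[0], float(dist[0])


def segment_closest_points_batch(A0, A1, B0, B1):
    """Vectorized closest-point computation between segment stacks.

    Implements the standard clamped two-parameter minimization (Ericson,
    *Real-Time Collision Detection*, ch. 5.1.9) with numpy broadcasting.
    Returns ``(pa, pb, distance)`` arrays.
    """
    A0 = np.asarray(A0, float)
    A1 = np.asarray(A1, float)
    B0 = np.asarray(B0, float)
    B1 = np.asarray(B1, float)
    d1 = A1 - A0
    d2 = B1 - B0
    r = A0 - B0
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = (b * s + f) / e
    t_low = t < 0.0
    t_high = t > 1.0
    t = np.clip(t, 0.0, 1.0)
    s = np.where(t_low, np.clip(-c / a, 0.0, 1.0), s)
    s = np.where(t_high, np.clip((b - c) / a, 0.0, 1.0), s)
    pa = A0 + s[..., None] * d1
    pb = B0 + t[..., None] * d2
    dist = np.linalg.norm(pa - pb, axis=-1)
    return pa, pb, dist
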