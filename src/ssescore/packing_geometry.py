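"""Fragment-pair packing descriptors.

The interaction of two SSE fragments is described by the analytically shortest
connection between their trimmed main-axis segments: its length ``d``, the
twist dihedral ``theta`` about the connection, per-strand offset angles
``omega`` and a contact weight that downgrades non-orthogonal connections.

Type-pair conventions:
  HH  helix-helix       interaction weight = contact weight
  HS  helix-strand      contact weight x offset weight (omega on the strand)
  SS  strand-strand     split into a pairing weight (omegas near 90 deg,
                        backbone-mediated) and a sandwich weight (omegas near
                        0 deg, side-chain mediated)
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import dihedral_batch, segment_closest_points_batch
from .model_io import HELIX, STRAND, SSE, Fragment
from .transitions import half_cosine_ramp

__all__ = [
    "FragmentPacking",
    "shortest_connection",
    "contact_weight",
    "offset_weight_helix_strand",
    "pairing_weight",
    "sandwich_weight",
    "packing_descriptors",
    "best_fragment_pairs",
    "descriptor_table",
]


@dataclass(frozen=True)
class FragmentPacking:
    """Geometric descriptor of one fragment pair."""

    type_pair: str  # "HH" | "HS" | "SS"
    distance: float  # shortest connection length (A)
    theta: float  # twist dihedral, degrees in (-180, 180]
    omega1: float | None  # offset angle of the first strand fragment [0, 90]
    omega2: float | None  # second strand fragment (SS only)
    contact_weight: float
    interaction_weight: float  # w_I, <= contact_weight
    weight_pairing: float = 0.0  # SS only: w_contact * pairing character
    weight_sandwich: float = 0.0  # SS only: w_contact * sandwich character
    frag_a: int = 0  # fragment index within first SSE
    frag_b: int = 0
    degenerate: bool = False


def _connection_angles(conn: np.ndarray, dist: np.ndarray, axes: np.ndarray):
    """Angle between the connection line and an axis, folded to [0, 90].

    90 deg means orthogonal (full contact).  Zero-length connections are
    degenerate; they report 90 deg (the fragments interpenetrate and the
    clash terms take over).
    """
    safe = np.where(dist[..., None] > 1e-9, dist[..., None], 1.0)
    u = conn / safe
    cosv = np.abs(np.sum(u * axes, axis=-1))
    ang = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    return np.where(dist > 1e-9, ang, 90.0)


def shortest_connection(seg_a: np.ndarray, seg_b: np.ndarray):
    """Shortest connection between two main-axis line segments.

    Parameters are ``(2, 3)`` endpoint arrays.  Returns
    ``(point_a, point_b, distance, angle_a, angle_b)`` where the angles are
    between the connection and each segment's axis, folded into [0, 90]
    degrees (90 = orthogonal).
    """
    seg_a = np.asarray(seg_a, float)
    seg_b = np.asarray(seg_b, float)
    for seg in (seg_a, seg_b):
        if np.linalg.norm(seg[1] - seg[0]) < 1e-9:
            raise ValueError("zero-length segment")
    pa, pb, dist = segment_closest_points_batch(
        seg_a[None, 0], seg_a[None, 1], seg_b[None, 0], seg_b[None, 1]
    )
    conn = pb - pa
    axis_a = (seg_a[1] - seg_a[0]) / np.linalg.norm(seg_a[1] - seg_a[0])
    axis_b = (seg_b[1] - seg_b[0]) / np.linalg.norm(seg_b[1] - seg_b[0])
    ang_a = _connection_angles(conn, dist, axis_a[None])
    ang_b = _connection_angles(conn, dist, axis_b[None])
    return pa[0], pb[0], float(dist[0]), float(ang_a[0]), float(ang_b[0])


def contact_weight(angle_a: float, angle_b: float) -> float:
    """Product of half-cosine ramps of both connection angles.

    1 when the connection is orthogonal to both axes (full contact), 0 when it
    is parallel to either.  Out-of-range angles are clamped with a warning.
    """
    for ang in (angle_a, angle_b):
        if not 0.0 <= ang <= 90.0:
            warnings.warn(f"connection angle {ang} outside [0, 90]; clamped")
    return float(half_cosine_ramp(angle_a) * half_cosine_ramp(angle_b))


def offset_weight_helix_strand(omega) -> np.ndarray | float:
    """1 when the strand face points at the helix (omega 0), 0 at 90 deg."""
    return 1.0 - half_cosine_ramp(omega)


def pairing_weight(omega1, omega2) -> np.ndarray | float:
    """Strand-strand backbone-pairing character; 1 when both omegas are 90."""
    return half_cosine_ramp(omega1) * half_cosine_ramp(omega2)


def sandwich_weight(omega1, omega2) -> np.ndarray | float:
    """Sheet-sandwich character; 1 when both omegas are 0."""
    return (1.0 - half_cosine_ramp(omega1)) * (1.0 - half_cosine_ramp(omega2))


def _type_pair(a: str, b: str) -> str:
    if a == HELIX and b == HELIX:
        return "HH"
    if a == STRAND and b == STRAND:
        return "SS"
    return "HS"


def _batch_descriptors(frags_a: list[Fragment], frags_b: list[Fragment]):
    """All-pairs descriptors between two fragment lists (vectorized).

    Returns a dict of ``(nA, nB)`` arrays.
    """
    A0 = np.array([f.effective_segment[0] for f in frags_a])
    A1 = np.array([f.effective_segment[1] for f in frags_a])
    B0 = np.array([f.effective_segment[0] for f in frags_b])
    B1 = np.array([f.effective_segment[1] for f in frags_b])
    axes_a = np.array([f.axis for f in frags_a])
    axes_b = np.array([f.axis for f in frags_b])
    nA, nB = len(frags_a), len(frags_b)
    pa, pb, dist = segment_closest_points_batch(
        A0[:, None], A1[:, None], B0[None, :], B1[None, :]
    )
    conn = pb - pa
    ang_a = _connection_angles(conn, dist, np.broadcast_to(axes_a[:, None], conn.shape))
    ang_b = _connection_angles(conn, dist, np.broadcast_to(axes_b[None, :], conn.shape))
    w_contact = half_cosine_ramp(ang_a) * half_cosine_ramp(ang_b)

    p0 = pa + np.broadcast_to(axes_a[:, None], conn.shape)
    p3 = pb + np.broadcast_to(axes_b[None, :], conn.shape)
    theta = dihedral_batch(p0, pa, pb, p3)

    def _omega(faces, direction):
        safe = np.where(dist[..., None] > 1e-9, dist[..., None], 1.0)
        u = direction / safe
        cosv = np.abs(np.sum(u * faces, axis=-1))
        om = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
        return np.where(dist > 1e-9, om, 0.0)

    omega1 = omega2 = None
    type_a = frags_a[0].sse_type
    type_b = frags_b[0].sse_type
    if type_a == STRAND:
        faces_a = np.broadcast_to(
            np.array([f.face for f in frags_a])[:, None], conn.shape
        )
        omega1 = _omega(faces_a, conn)
    if type_b == STRAND:
        faces_b = np.broadcast_to(
            np.array([f.face for f in frags_b])[None, :], conn.shape
        )
        omega2 = _omega(faces_b, -conn)

    tp = _type_pair(type_a, type_b)
    w_pair = np.zeros((nA, nB))
    w_sand = np.zeros((nA, nB))
    if tp == "HH":
        w_int = w_contact
    elif tp == "SS":
        w_pair = w_contact * pairing_weight(omega1, omega2)
        w_sand = w_contact * sandwich_weight(omega1, omega2)
        w_int = w_pair + w_sand
    else:
        om = omega1 if type_a == STRAND else omega2
        w_int = w_contact * offset_weight_helix_strand(om)
    return {
        "type_pair": tp,
        "distance": dist,
        "theta": theta,
        "omega1": omega1,
        "omega2": omega2,
        "contact_weight": w_contact,
        "interaction_weight": w_int,
        "weight_pairing": w_pair,
        "weight_sandwich": w_sand,
        "degenerate": dist <= 1e-9,
    }


def _packing_from_batch(batch, i: int, j: int) -> FragmentPacking:
    def _get(key):
        arr = batch[key]
        return None if arr is None else float(arr[i, j])

    return FragmentPacking(
        type_pair=batch["type_pair"],
        distance=float(batch["distance"][i, j]),
        theta=float(batch["theta"][i, j]),
        omega1=_get("omega1"),
        omega2=_get("omega2"),
        contact_weight=float(batch["contact_weight"][i, j]),
        interaction_weight=float(batch["interaction_weight"][i, j]),
        weight_pairing=float(batch["weight_pairing"][i, j]),
        weight_sandwich=float(batch["weight_sandwich"][i, j]),
        frag_a=i,
        frag_b=j,
        degenerate=bool(batch["degenerate"][i, j]),
    )


def packing_descriptors(frag_a: Fragment, frag_b: Fragment) -> FragmentPacking:
    """Full packing descriptor for a single fragment pair."""
    batch = _batch_descriptors([frag_a], [frag_b])
    return _packing_from_batch(batch, 0, 0)


def best_fragment_pairs(sse_a: SSE, sse_b: SSE) -> list[FragmentPacking]:
    """Interaction list of two SSEs.

    For every fragment of the shorter SSE (ties: the SSE earlier in sequence
    counts as shorter) the partner fragment of the longer SSE with the highest
    interaction weight is selected, so the list has as many entries as the
    shorter SSE has fragments.
    """
    fa, fb = sse_a.fragments, sse_b.fragments
    if not fa or not fb:
        return []
    na, nb = len(fa), len(fb)
    a_is_short = na < nb or (
        na == nb and (sse_a.chain_id, sse_a.first_seq) <= (sse_b.chain_id, sse_b.first_seq)
    )
    if a_is_short:
        batch = _batch_descriptors(fa, fb)
        best = np.argmax(batch["interaction_weight"], axis=1)
        return [_packing_from_batch(batch, i, int(j)) for i, j in enumerate(best)]
    batch = _batch_descriptors(fa, fb)
    best = np.argmax(batch["interaction_weight"], axis=0)
    return [_packing_from_batch(batch, int(i), j) for j, i in enumerate(best)]


def descriptor_table(model) -> pd.DataFrame:
    """Tabular dump of all selected fragment-pair descriptors of a model."""
    rows = []
    sses = [s for s in model.sses if s.include_in_packing and s.fragments]
    for i, sa in enumerate(sses):
        for j in range(i + 1, len(sses)):
            sb = sses[j]
            for p in best_fragment_pairs(sa, sb):
                rows.append(
                    {
                        "sse_a": i,
                        "sse_b": j,
                        "frag_a": p.frag_a,
                        "frag_b": p.frag_b,
                        "type_pair": p.type_pair,
                        "distance": p.distance,
                        "theta": p.theta,
                        "omega1": p.omega1,
                        "omega2": p.omega2,
                        "w_contact": p.contact_weight,
                        "w_interaction": p.interaction_weight,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sse_a", "sse_b", "frag_a", "frag_b", "type_pair", "distance",
            "theta", "omega1", "omega2", "w_contact", "w_interaction",
        ],
    )
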