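"""Idealized secondary-structure geometry.

Coordinates for ideal helices and strands are generated parametrically about a
straight main axis along +z, with residue 0 at z = 0.  These serve both as
superposition templates for fragment axis fitting and as building blocks for
the synthetic fixture generator.

Template geometry (the classic textbook values):
  helix:  1.5 A rise/residue, 100 deg turn/residue, C-alpha radius 2.3 A
  strand: 3.4 A rise/residue, alternating 0.4 A pleat
"""
from __future__ import annotations

import numpy as np

HELIX = "H"
STRAND = "E"

FRAGMENT_LENGTH = {HELIX: 5, STRAND: 3}
#: SSEs shorter than this are excluded from packing statistics and scores.
MIN_PACKING_LENGTH = {HELIX: 7, STRAND: 5}

HELIX_RISE = 1.5
HELIX_TURN = 100.0
HELIX_CA_RADIUS = 2.3
HELIX_CB_RADIUS = 3.3

STRAND_RISE = 3.4
STRAND_PLEAT = 0.4
CA_CB_LENGTH = 1.53


def _helix_curve(t: np.ndarray, radius: float) -> np.ndarray:
    ang = np.radians(HELIX_TURN) * t
    return np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), HELIX_RISE * t], axis=-1
    )


def ideal_ca(sse_type: str, n: int) -> np.ndarray:
    """C-alpha coordinates of an ideal SSE of ``n`` residues, axis along +z."""
    i = np.arange(n, dtype=float)
    if sse_type == HELIX:
        return _helix_curve(i, HELIX_CA_RADIUS)
    if sse_type == STRAND:
        pleat = STRAND_PLEAT * np.where(i.astype(int) % 2 == 0, 1.0, -1.0)
        return np.stack([pleat, np.zeros(n), STRAND_RISE * i], axis=-1)
    raise ValueError(f"unknown SSE type {sse_type!r}")


def ideal_backbone(sse_type: str, n: int) -> dict[str, np.ndarray]:
    """N/CA/C/CB coordinates of an ideal SSE, axis along +z.

    Backbone N and C are placed along the local chain direction; CB anchors
    point radially outward (helix) or alternate across the strand plane
    (strand), which is what gives strand fragments a well-defined face.
    """
    ca = ideal_ca(sse_type, n)
    i = np.arange(n, dtype=float)
    if sse_type == HELIX:
        natm = _helix_curve(i - 0.35, HELIX_CA_RADIUS)
        catm = _helix_curve(i + 0.35, HELIX_CA_RADIUS)
        cb = _helix_curve(i, HELIX_CB_RADIUS)
    else:
        off = np.array([0.0, 0.0, 1.2])
        natm = ca - off
        catm = ca + off
        side = np.where(i.astype(int) % 2 == 0, 1.0, -1.0)
        cb = ca + np.stack(
            [CA_CB_LENGTH * side, np.zeros(n), np.zeros(n)], axis=-1
        )
    return {"N": natm, "CA": ca, "C": catm, "CB": cb}


def template_ca(sse_type: str, length: int | None = None) -> np.ndarray:
    """Centered C-alpha template used for fragment-axis superposition."""
    if length is None:
        length = FRAGMENT_LENGTH[sse_type]
    ca = ideal_ca(sse_type, length)
    return ca - ca.mean(axis=0)


def rise_per_residue(sse_type: str) -> float:
    return HELIX_RISE if sse_type == HELIX else STRAND_RISE
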