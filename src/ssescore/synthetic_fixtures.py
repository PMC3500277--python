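"""Synthetic structure generator: ideal SSEs, toy topologies, decoys.

Everything any other module needs for testing and training is generated here:
ideal helix/strand coordinates assembled into small folds, perturbation
decoys (SSE rotation/translation, flip, swap, removal), a fixture training
database and synthetic secondary-structure prediction files.  All generators
are pure functions of their spec and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ideal
from ._geometry import kabsch, random_rotation, rotation_about_axis, unit
from .energy_terms import SSAgreementParams
from .model_io import (AA1, AA1_TO_3, AA3_TO_1, HELIX, STRAND, AminoAcid,
                       ProteinModel, SSE)

__all__ = [
    "TopologySpec",
    "ideal_sse",
    "make_toy_protein",
    "perturb_model",
    "make_decoy",
    "ca_rmsd",
    "make_fixture_database",
    "synth_predictions",
    "topology_catalog",
]

_IDENTITY = np.eye(3)


@dataclass
class TopologySpec:
    """Recipe for a toy protein.

    ``elements`` holds ``(sse_type, length, R, t)`` placements applied to the
    centered ideal SSE; ``loop_gaps`` are the sequence gaps between
    consecutive elements.  The sequence (one-letter codes) is drawn randomly
    when absent.
    """

    elements: list
    loop_gaps: list
    sequence: str | None = None
    name: str = "toy"

    def __post_init__(self):
        if len(self.loop_gaps) != max(0, len(self.elements) - 1):
            raise ValueError("need one loop gap per consecutive element pair")


def ideal_sse(sse_type: str, n: int, sequence: str,
              chain_id: str = "A", start_seq: int = 1,
              R: np.ndarray = _IDENTITY, t: np.ndarray = None) -> SSE:
    """Ideal SSE with backbone and anchors, centered then rigidly placed."""
    if len(sequence) != n:
        raise ValueError("sequence length must match residue count")
    if t is None:
        t = np.zeros(3)
    bb = ideal.ideal_backbone(sse_type, n)
    center = bb["CA"].mean(axis=0)
    residues = []
    for i in range(n):
        coords = {k: (bb[k][i] - center) @ np.asarray(R).T + t for k in bb}
        residues.append(
            AminoAcid(
                chain_id, start_seq + i, AA1_TO_3[sequence[i]],
                anchor=coords["CB"],
                backbone={k: coords[k] for k in ("N", "CA", "C")},
            )
        )
    return SSE(sse_type, residues)


#: fixture sequences draw from a reduced alphabet so that pair-distance
#: statistics are not hopelessly sparse at fixture-database scale
FIXTURE_ALPHABET = "ADEFGIKLRV"


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FIXTURE_ALPHABET), size=n))


def make_toy_protein(spec: TopologySpec, seed: int = 0) -> ProteinModel:
    """Deterministic assembly of a topology spec into a reduced model."""
    rng = np.random.default_rng(seed)
    total = sum(length for _, length, _, _ in spec.elements)
    sequence = spec.sequence or _random_sequence(rng, total)
    if len(sequence) != total:
        raise ValueError("sequence length must match total SSE residues")
    sses = []
    seq_pos = 0
    next_seq = 1
    for k, (sse_type, length, R, t) in enumerate(spec.elements):
        sses.append(
            ideal_sse(sse_type, length, sequence[seq_pos:seq_pos + length],
                      start_seq=next_seq, R=R, t=np.asarray(t, float))
        )
        seq_pos += length
        next_seq += length
        if k < len(spec.loop_gaps):
            next_seq += int(spec.loop_gaps[k])
    return ProteinModel(sses, name=spec.name)


# ---------------------------------------------------------------------------
# topology catalog


def _flip_x() -> np.ndarray:
    return rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)


def _tilt_y(rng: np.random.Generator, sign: int) -> np.ndarray:
    """Small helix crossing tilt (real bundles pack at ~10-25 deg)."""
    return rotation_about_axis(np.array([0.0, 1.0, 0.0]),
                               sign * float(rng.uniform(6.0, 12.0)))


def two_helix_bundle(rng: np.random.Generator) -> TopologySpec:
    n = int(rng.integers(10, 15))
    spacing = float(rng.uniform(9.5, 11.0))
    elements = [
        (HELIX, n, _tilt_y(rng, 1), np.zeros(3)),
        (HELIX, n, _tilt_y(rng, -1) @ _flip_x(), np.array([spacing, 0.0, 0.0])),
    ]
    return TopologySpec(elements, [3], name="two_helix_bundle")


def three_helix_bundle(rng: np.random.Generator) -> TopologySpec:
    n = int(rng.integers(10, 14))
    s = float(rng.uniform(9.5, 11.0))
    positions = [np.array([0.0, 0.0, 0.0]), np.array([s, 0.0, 0.0]),
                 np.array([s / 2, s * 0.87, 0.0])]
    elements = []
    for k, pos in enumerate(positions):
        R = _flip_x() if k % 2 else _IDENTITY
        elements.append((HELIX, n, _tilt_y(rng, 1 if k % 2 else -1) @ R, pos))
    return TopologySpec(elements, [3, 3], name="three_helix_bundle")


def four_helix_bundle(rng: np.random.Generator) -> TopologySpec:
    n = int(rng.integers(10, 13))
    s = float(rng.uniform(9.5, 11.0))
    positions = [np.array([0.0, 0.0, 0.0]), np.array([s, 0.0, 0.0]),
                 np.array([s, s, 0.0]), np.array([0.0, s, 0.0])]
    elements = []
    for k, pos in enumerate(positions):
        R = _flip_x() if k % 2 else _IDENTITY
        elements.append((HELIX, n, _tilt_y(rng, 1 if k % 2 else -1) @ R, pos))
    return TopologySpec(elements, [3, 3, 3], name="four_helix_bundle")


def antiparallel_sheet(rng: np.random.Generator,
                       n_strands: int = 3) -> TopologySpec:
    n = int(rng.integers(5, 8))
    spacing = float(rng.uniform(4.6, 4.9))
    twist = float(rng.uniform(10.0, 20.0))
    elements = []
    for k in range(n_strands):
        R = _flip_x() if k % 2 else _IDENTITY
        R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), k * twist) @ R
        elements.append((STRAND, n, R, np.array([0.0, k * spacing, 0.0])))
    return TopologySpec(elements, [2] * (n_strands - 1),
                        name=f"antiparallel_sheet{n_strands}")


def parallel_sheet(rng: np.random.Generator) -> TopologySpec:
    n = int(rng.integers(5, 7))
    spacing = float(rng.uniform(4.6, 4.9))
    twist = float(rng.uniform(10.0, 20.0))
    elements = []
    for k in range(3):
        R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), k * twist)
        elements.append((STRAND, n, R, np.array([0.0, k * spacing, 0.0])))
    # crossover loops must span the strand length
    gap = int(np.ceil((n * ideal.STRAND_RISE) / 2.4)) + 1
    return TopologySpec(elements, [gap, gap], name="parallel_sheet")


def helix_on_sheet(rng: np.random.Generator) -> TopologySpec:
    sheet = antiparallel_sheet(rng, 3)
    n_helix = int(rng.integers(10, 13))
    offset = float(rng.uniform(9.5, 11.0))
    elements = sheet.elements + [
        (HELIX, n_helix, _tilt_y(rng, 1) @ _flip_x(),
         np.array([offset, 4.75, 0.0]))
    ]
    return TopologySpec(elements, sheet.loop_gaps + [4], name="helix_on_sheet")


def beta_sandwich(rng: np.random.Generator) -> TopologySpec:
    sheet_a = antiparallel_sheet(rng, 3)
    offset = float(rng.uniform(9.5, 11.0))
    elements = list(sheet_a.elements)
    for k, (sse_type, length, R, t) in enumerate(antiparallel_sheet(rng, 3).elements):
        flip = _flip_x() if k % 2 == 0 else _IDENTITY  # reverse threading order
        elements.append((sse_type, length, R @ flip,
                         np.asarray(t) + np.array([offset, 0.0, 0.0])))
    return TopologySpec(elements, sheet_a.loop_gaps + [4] + [2, 2],
                        name="beta_sandwich")


def topology_catalog():
    """The toy topology builders used for fixtures and benchmarks."""
    return [
        two_helix_bundle,
        three_helix_bundle,
        four_helix_bundle,
        lambda rng: antiparallel_sheet(rng, 3),
        lambda rng: antiparallel_sheet(rng, 4),
        parallel_sheet,
        helix_on_sheet,
        beta_sandwich,
    ]


def make_fixture_database(n_proteins: int = 50, seed: int = 0) -> list[ProteinModel]:
    """Varied toy natives for training statistics; deterministic under seed."""
    rng = np.random.default_rng(seed)
    builders = topology_catalog()
    models = []
    for i in range(n_proteins):
        spec = builders[i % len(builders)](rng)
        model = make_toy_protein(spec, seed=int(rng.integers(0, 2 ** 31)))
        model.name = f"fix{i:03d}_{spec.name}"
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# perturbation decoys


def _sse_frame(sse: SSE) -> tuple[np.ndarray, np.ndarray]:
    """(origin, orthonormal frame) of an SSE; exact for identical copies."""
    ca = sse.ca_coords()
    origin = ca.mean(axis=0)
    z = unit(ca[-1] - ca[0])
    v = sse.residues[0].anchor - origin
    v = v - (v @ z) * z
    if np.linalg.norm(v) < 1e-9:
        v = np.array([1.0, 0.0, 0.0])
        v = v - (v @ z) * z
    x = unit(v)
    y = np.cross(z, x)
    return origin, np.column_stack([x, y, z])


def _transform_about(sse: SSE, R: np.ndarray, center: np.ndarray,
                     shift: np.ndarray | None = None) -> SSE:
    t = center - R @ center
    if shift is not None:
        t = t + shift
    return sse.transformed(R, t)


MOVES = ("rotate_translate", "flip", "swap", "remove")


def perturb_model(model: ProteinModel, move: str, rng: np.random.Generator,
                  max_rotation: float = 60.0,
                  max_translation: float = 8.0) -> ProteinModel:
    """Apply exactly one perturbation move; the input model is untouched."""
    sses = [s.copy() for s in model.sses]
    if move == "remove" and len(sses) <= 2:
        move = "rotate_translate"
    if move == "rotate_translate":
        k = int(rng.integers(len(sses)))
        R = random_rotation(rng, max_rotation)
        direction = rng.normal(size=3)
        direction = direction / np.linalg.norm(direction)
        shift = direction * max_translation * rng.random() ** (1 / 3)
        center = sses[k].ca_coords().mean(axis=0)
        sses[k] = _transform_about(sses[k], R, center, shift)
    elif move == "flip":
        k = int(rng.integers(len(sses)))
        ca = sses[k].ca_coords()
        frags = sses[k].fragments
        if frags:
            axis = unit(np.mean([f.axis for f in frags], axis=0))
        else:
            axis = unit(ca[-1] - ca[0])
        perp = rng.normal(size=3)
        perp = perp - (perp @ axis) * axis
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
        R = rotation_about_axis(perp, 180.0)
        sses[k] = _transform_about(sses[k], R, ca.mean(axis=0))
    elif move == "swap":
        i, j = rng.choice(len(sses), size=2, replace=False)
        oi, Fi = _sse_frame(sses[i])
        oj, Fj = _sse_frame(sses[j])
        Rij = Fj @ Fi.T
        Rji = Fi @ Fj.T
        new_i = sses[i].transformed(Rij, oj - Rij @ oi)
        new_j = sses[j].transformed(Rji, oi - Rji @ oj)
        sses[i], sses[j] = new_i, new_j
    elif move == "remove":
        k = int(rng.integers(len(sses)))
        sses.pop(k)
    else:
        raise ValueError(f"unknown move {move!r}")
    return ProteinModel(sses, n_residues=model.n_residues, name=model.name)


def make_decoy(native: ProteinModel, rng: np.random.Generator,
               n_moves: int = 3, heavy: bool = True) -> ProteinModel:
    """Compound decoy: several random perturbation moves applied in sequence.

    ``heavy=False`` yields near-native decoys (small rigid moves only).
    """
    model = native
    if not heavy:
        for _ in range(n_moves):
            model = perturb_model(model, "rotate_translate", rng,
                                  max_rotation=6.0, max_translation=0.6)
        return model
    move_p = np.array([0.55, 0.2, 0.15, 0.1])
    for _ in range(n_moves):
        move = MOVES[int(rng.choice(4, p=move_p))]
        model = perturb_model(model, move, rng)
    return model


def ca_rmsd(native: ProteinModel, model: ProteinModel) -> float:
    """C-alpha RMSD after optimal superposition over common residues."""
    nat = {(r.chain_id, r.seq_id): r.ca for r in native.residues}
    mod = {(r.chain_id, r.seq_id): r.ca for r in model.residues}
    common = sorted(set(nat) & set(mod))
    if len(common) < 3:
        raise ValueError("too few common residues for superposition")
    P = np.array([mod[k] for k in common])
    Q = np.array([nat[k] for k in common])
    R, t = kabsch(P, Q)
    return float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# synthetic predictions


def synth_predictions(model: ProteinModel, accuracy: float,
                      rng: np.random.Generator,
                      method: str = "psipred",
                      params: SSAgreementParams | None = None) -> dict:
    """Per-residue 3-state probabilities matching the method's statistics.

    Covers all ``1..n_residues`` positions (non-SSE residues are treated as
    coil).  With probability ``accuracy`` the assigned state's probability is
    drawn from a normal with the method's (mu, sigma); otherwise the weight
    goes to a randomly chosen other state.  Returns ``{seq_id: (pC, pH, pE)}``.
    """
    params = params or SSAgreementParams()
    state_of: dict[int, str] = {}
    for sse in model.sses:
        state = "H" if sse.sse_type == HELIX else "E"
        for res in sse.residues:
            state_of[res.seq_id] = state
    out = {}
    states = ("C", "H", "E")
    for seq_id in range(1, model.n_residues + 1):
        true_state = state_of.get(seq_id, "C")
        if rng.random() < accuracy:
            top_state = true_state
        else:
            top_state = states[int(rng.choice([s for s in range(3)
                                               if states[s] != true_state]))]
        mu, sigma = params.mu_sigma(method, top_state)
        p_top = float(np.clip(rng.normal(mu, sigma), 0.02, 0.98))
        u = rng.random()
        rest = 1.0 - p_top
        probs = {s: 0.0 for s in states}
        probs[top_state] = p_top
        others = [s for s in states if s != top_state]
        probs[others[0]] = rest * u
        probs[others[1]] = rest * (1.0 - u)
        out[seq_id] = (probs["C"], probs["H"], probs["E"])
    return out


def predictions_to_ss2_rows(model: ProteinModel, predictions: dict):
    """Rows for :func:`ssescore.model_io.write_ss2`."""
    aa_of = {r.seq_id: AA3_TO_1[r.aa_type] for r in model.residues}
    state_of = {}
    for sse in model.sses:
        for r in sse.residues:
            state_of[r.seq_id] = "H" if sse.sse_type == HELIX else "E"
    rows = []
    for seq_id in sorted(predictions):
        pc, ph, pe = predictions[seq_id]
        rows.append((seq_id, aa_of.get(seq_id, "A"),
                     state_of.get(seq_id, "C"), pc, ph, pe))
    return rows
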