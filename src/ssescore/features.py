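"""Geometric features extracted from reduced models.

Shared by the statistics builder (which histograms them over a training set)
and the scoring terms (which evaluate energy tables on them).
"""
from __future__ import annotations

import numpy as np

from .model_io import AA_INDEX, ProteinModel, SSE
from .packing_geometry import FragmentPacking, best_fragment_pairs
from .transitions import step_down

#: neighbor-count transition thresholds (A)
NC_LOWER = 4.0
NC_UPPER = 11.4
#: minimal sequence separation for the environment / neighbor count
NC_MIN_SEQ_SEP = 3
#: minimal sequence separation for amino acid pair features
PAIR_MIN_SEQ_SEP = 12
#: heavy-atom contact cutoff for contact order (anchor-anchor here)
CONTACT_ORDER_CUTOFF = 8.0


def model_arrays(model: ProteinModel):
    """(anchors, seq_ids, chain_index, aa_index) arrays over SSE residues."""
    res = model.residues
    if not res:
        return (np.zeros((0, 3)), np.zeros(0, int), np.zeros(0, int),
                np.zeros(0, int))
    chains = {c: i for i, c in enumerate(model.chains)}
    anchors = np.array([r.anchor for r in res])
    seq = np.array([r.seq_id for r in res])
    chain = np.array([chains[r.chain_id] for r in res])
    aa = np.array([AA_INDEX[r.aa_type] for r in res])
    return anchors, seq, chain, aa


def _pair_mask(seq: np.ndarray, chain: np.ndarray, min_sep: int) -> np.ndarray:
    sep = np.abs(seq[:, None] - seq[None, :])
    same_chain = chain[:, None] == chain[None, :]
    return (~same_chain) | (sep >= min_sep)


def neighbor_counts(model: ProteinModel) -> np.ndarray:
    """Smoothed neighbor count per SSE residue.

    Each neighbor at anchor distance d contributes a half-cosine weight that
    drops from 1 at ``NC_LOWER`` to 0 at ``NC_UPPER``; residues closer than
    ``NC_MIN_SEQ_SEP`` in sequence are ignored.
    """
    anchors, seq, chain, _ = model_arrays(model)
    n = len(seq)
    if n == 0:
        return np.zeros(0)
    diff = anchors[:, None, :] - anchors[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    w = step_down(dist, NC_LOWER, NC_UPPER)
    eligible = _pair_mask(seq, chain, NC_MIN_SEQ_SEP)
    np.fill_diagonal(eligible, False)
    return np.sum(np.where(eligible, w, 0.0), axis=1)


def pair_distance_features(model: ProteinModel):
    """(aa_i, aa_j, distance) arrays for unordered residue pairs, sep >= 12."""
    anchors, seq, chain, aa = model_arrays(model)
    n = len(seq)
    if n < 2:
        return np.zeros(0, int), np.zeros(0, int), np.zeros(0)
    iu, ju = np.triu_indices(n, k=1)
    mask = _pair_mask(seq, chain, PAIR_MIN_SEQ_SEP)[iu, ju]
    iu, ju = iu[mask], ju[mask]
    dist = np.linalg.norm(anchors[iu] - anchors[ju], axis=1)
    return aa[iu], aa[ju], dist


def contact_order_norm(model: ProteinModel) -> float:
    """Squared contact order over sequence length.

    Contact order is the mean sequence separation of residue pairs whose
    anchors lie within ``CONTACT_ORDER_CUTOFF``; returns ``CO^2 / n_residues``
    (0 when there are no contacts).
    """
    anchors, seq, chain, _ = model_arrays(model)
    n = len(seq)
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    same = chain[iu] == chain[ju]
    dist = np.linalg.norm(anchors[iu] - anchors[ju], axis=1)
    mask = same & (dist <= CONTACT_ORDER_CUTOFF)
    if not np.any(mask):
        return 0.0
    co = float(np.mean(np.abs(seq[iu[mask]] - seq[ju[mask]])))
    return co ** 2 / model.n_residues


def radius_of_gyration_norm(model: ProteinModel) -> float:
    """Mean squared anchor distance to the centroid over sequence length."""
    anchors = model.anchors()
    if len(anchors) == 0:
        return 0.0
    centered = anchors - anchors.mean(axis=0)
    r2 = float(np.mean(np.sum(centered ** 2, axis=1)))
    return r2 / model.n_residues


def squared_radius_of_gyration(model: ProteinModel) -> float:
    """Unnormalized mean squared anchor distance to the centroid."""
    anchors = model.anchors()
    if len(anchors) == 0:
        return 0.0
    centered = anchors - anchors.mean(axis=0)
    return float(np.mean(np.sum(centered ** 2, axis=1)))


def _sequence_tip(sse: SSE, end: bool) -> np.ndarray:
    """Main-axis tip of the first/last fragment facing a loop.

    Falls back to the terminal C-alpha for SSEs too short to carry fragments.
    """
    frags = sse.fragments
    if not frags:
        return sse.residues[-1 if end else 0].ca
    if end:
        return frags[-1].full_segment[1]
    return frags[0].full_segment[0]


def loop_features(model: ProteinModel):
    """Per consecutive same-chain SSE pair: (n_loop, tip_distance, d_CN).

    ``n_loop`` is the number of loop residues between the SSEs,
    ``tip_distance`` the Euclidean distance between the facing main-axis tips
    and ``d_CN`` the distance between the terminal backbone C atom and the
    next SSE's starting N atom (anchor-based approximation when backbone
    atoms are missing).
    """
    out = []
    for a, b in zip(model.sses, model.sses[1:]):
        if a.chain_id != b.chain_id:
            continue
        n_loop = b.first_seq - a.last_seq - 1
        tip_d = float(np.linalg.norm(_sequence_tip(b, False) - _sequence_tip(a, True)))
        ra, rb = a.residues[-1], b.residues[0]
        c_atom = ra.backbone.get("C") if ra.backbone else None
        n_atom = rb.backbone.get("N") if rb.backbone else None
        if c_atom is None:
            c_atom = ra.ca
        if n_atom is None:
            n_atom = rb.ca
        d_cn = float(np.linalg.norm(n_atom - c_atom))
        out.append((n_loop, tip_d, d_cn))
    return out


def packing_contacts(model: ProteinModel) -> list[FragmentPacking]:
    """Selected fragment-pair interactions over all eligible SSE pairs."""
    sses = [s for s in model.sses if s.include_in_packing and s.fragments]
    out: list[FragmentPacking] = []
    for i, sa in enumerate(sses):
        for sb in sses[i + 1:]:
            out.extend(best_fragment_pairs(sa, sb))
    return out
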