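"""The twelve scoring terms.

Eight statistical potentials (amino acid pair distance, environment, loop
length, strand pairing, SSE packing, contact order, radius of gyration, and
the secondary-structure prediction agreement for two prediction methods
counted separately) plus three penalty terms (amino acid clash, SSE clash,
loop closure).  Every term maps a reduced model to an energy; lower is better.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import erf

from . import features
from .model_io import AA3, AA_INDEX, HELIX, STRAND, ProteinModel
from .statistics_builder import TableSet, pair_key

TERM_NAMES = (
    "aa_clash",
    "aa_distance",
    "aa_neighbor",
    "contact_order",
    "loop_length",
    "loop_closure",
    "radius_of_gyration",
    "sse_clash",
    "sse_packing",
    "strand_pairing",
    "ss_jufo",
    "ss_psipred",
)

#: per-method, per-state (H, E, C) mean/sd of correctly predicted probabilities
DEFAULT_SS_STATS = {
    "jufo": {"H": (0.67, 0.21), "E": (0.58, 0.24), "C": (0.59, 0.18)},
    "psipred": {"H": (0.76, 0.20), "E": (0.71, 0.27), "C": (0.73, 0.21)},
}


@dataclass
class SSAgreementParams:
    """Mean/sd of the predicted probability of correctly predicted residues."""

    stats: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_SS_STATS.items()
    })

    def mu_sigma(self, method: str, state: str) -> tuple[float, float]:
        mu, sigma = self.stats[method][state]
        if not 0.0 < mu < 1.0 or sigma <= 0.0:
            raise ValueError("invalid SS agreement parameters")
        return mu, sigma


#: minimal fragment-fragment distances per SSE type pair (A)
DEFAULT_SSE_MIN_DISTANCE = {"HH": 4.0, "HS": 4.0, "SS": 3.0}


@dataclass
class ClashParams:
    """Penalty-term parameters.

    ``aa_min_distance`` is the symmetric 20x20 matrix of shortest allowed
    anchor distances.  ``loop_closure_slope/intercept`` define the maximal
    bridgeable end-to-end distance per loop residue.
    """

    aa_min_distance: np.ndarray
    sse_min_distance: dict = field(
        default_factory=lambda: dict(DEFAULT_SSE_MIN_DISTANCE)
    )
    ramp_width: float = 1.0  # full penalty this far below the allowed distance
    loop_closure_slope: float = 2.6  # A per loop residue
    loop_closure_intercept: float = 4.0  # A
    loop_closure_exponent: float = 2.0

    def __post_init__(self):
        self.aa_min_distance = np.asarray(self.aa_min_distance, float)
        if self.aa_min_distance.shape != (20, 20):
            raise ValueError("aa_min_distance must be 20x20")
        if not np.allclose(self.aa_min_distance, self.aa_min_distance.T):
            raise ValueError("aa_min_distance must be symmetric")
        if np.any(self.aa_min_distance <= 0):
            raise ValueError("distances must be positive")

    def to_json(self, path) -> None:
        payload = {
            "aa_min_distance": np.round(self.aa_min_distance, 4).tolist(),
            "sse_min_distance": self.sse_min_distance,
            "ramp_width": self.ramp_width,
            "loop_closure_slope": self.loop_closure_slope,
            "loop_closure_intercept": self.loop_closure_intercept,
            "loop_closure_exponent": self.loop_closure_exponent,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ClashParams":
        d = json.loads(Path(path).read_text())
        return cls(
            aa_min_distance=np.array(d["aa_min_distance"]),
            sse_min_distance=dict(d["sse_min_distance"]),
            ramp_width=d["ramp_width"],
            loop_closure_slope=d["loop_closure_slope"],
            loop_closure_intercept=d["loop_closure_intercept"],
            loop_closure_exponent=d.get("loop_closure_exponent", 2.0),
        )


def default_clash_params() -> ClashParams:
    """Bundled fixture-derived clash parameters."""
    with resources.as_file(
        resources.files("ssescore.data") / "default_params.json"
    ) as path:
        return ClashParams.from_json(path)


# ---------------------------------------------------------------------------
# statistical terms


def neighbor_count(residue_index: int, model: ProteinModel) -> float:
    """Smoothed neighbor count of one SSE residue (by flat residue index)."""
    return float(features.neighbor_counts(model)[residue_index])


def score_environment(model: ProteinModel, env_tables: dict) -> float:
    """Sum of per-residue neighbor-count energies."""
    nc = features.neighbor_counts(model)
    total = 0.0
    for res, value in zip(model.residues, nc):
        total += env_tables[res.aa_type].evaluate(value)
    return total


def score_aa_pair(model: ProteinModel, pair_tables: dict) -> float:
    """Sum over SSE residue pairs (sequence separation >= 12) of the
    type-pair distance potential; pairs beyond table support contribute 0."""
    ai, aj, dist = features.pair_distance_features(model)
    if len(dist) == 0:
        return 0.0
    total = 0.0
    keys = np.array([pair_key(AA3[a], AA3[b]) for a, b in zip(ai, aj)])
    for key in np.unique(keys):
        table = pair_tables[key]
        sel = dist[keys == key]
        support = table.centers[0][-1] + (table.centers[0][1] - table.centers[0][0])
        sel = sel[sel <= support]
        if len(sel):
            total += float(np.sum(table.evaluate(sel)))
    return total


def score_loop_length(model: ProteinModel, loop_table) -> float:
    """Loop (sequence distance, axis-tip distance) energies over consecutive
    SSE pairs."""
    total = 0.0
    for n_loop, tip_d, _ in features.loop_features(model):
        total += loop_table.evaluate(float(n_loop), tip_d)
    return total


def score_sse_contacts(model: ProteinModel, packing_tables: dict) -> dict:
    """Strand-pairing and SSE-packing energies from fragment interactions.

    Strand-strand interactions are apportioned between the pairing and the
    sandwich table by their omega-derived weights; helix-helix and
    helix-strand contributions go to the packing score.
    """
    pairing = 0.0
    packing = 0.0
    for p in features.packing_contacts(model):
        if p.type_pair == "SS":
            if p.weight_pairing > 0:
                pairing += p.weight_pairing * packing_tables["SS_PAIR"].evaluate(
                    p.distance, p.theta
                )
            if p.weight_sandwich > 0:
                packing += p.weight_sandwich * packing_tables["SS_SAND"].evaluate(
                    p.distance, p.theta
                )
        elif p.interaction_weight > 0:
            packing += p.interaction_weight * packing_tables[p.type_pair].evaluate(
                p.distance, p.theta
            )
    return {"strand_pairing": pairing, "sse_packing": packing}


def contact_order_norm(model: ProteinModel) -> float:
    return features.contact_order_norm(model)


def radius_of_gyration_norm(model: ProteinModel) -> float:
    return features.radius_of_gyration_norm(model)


def score_contact_order(model: ProteinModel, table) -> float:
    return table.evaluate(features.contact_order_norm(model))


def score_radius_gyration(model: ProteinModel, table) -> float:
    return table.evaluate(features.radius_of_gyration_norm(model))


def score_ss_agreement(model: ProteinModel, predictions: dict,
                       method: str,
                       params: SSAgreementParams | None = None) -> float:
    """Agreement of assigned SSE states with per-residue predictions.

    For each SSE residue the standard score of the predicted probability of
    the assigned state is mapped through the error function:
    ``-erf(z / sqrt(2))`` (negative when the prediction supports the model).
    Raises ``KeyError`` when a residue lacks a prediction.
    """
    params = params or SSAgreementParams()
    total = 0.0
    for sse in model.sses:
        state = "H" if sse.sse_type == HELIX else "E"
        mu, sigma = params.mu_sigma(method, state)
        for res in sse.residues:
            pc, ph, pe = predictions[res.seq_id]
            p = ph if state == "H" else pe
            z = (p - mu) / sigma
            total += -erf(z / np.sqrt(2.0))
    return float(total)


# ---------------------------------------------------------------------------
# penalty terms


def _ramp_penalty(dist, d_min, width):
    """0 at/above d_min, rising linearly to 1 at d_min - width, capped at 1."""
    return np.clip((d_min - dist) / width, 0.0, 1.0)


def score_aa_clash(model: ProteinModel, params: ClashParams) -> float:
    """Penalty for residue pairs closer than the type-pair minimum distance."""
    anchors, seq, chain, aa = features.model_arrays(model)
    n = len(seq)
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    mask = features._pair_mask(seq, chain, features.NC_MIN_SEQ_SEP)[iu, ju]
    iu, ju = iu[mask], ju[mask]
    dist = np.linalg.norm(anchors[iu] - anchors[ju], axis=1)
    d_min = params.aa_min_distance[aa[iu], aa[ju]]
    return float(np.sum(_ramp_penalty(dist, d_min, params.ramp_width)))


def score_sse_clash(model: ProteinModel, params: ClashParams) -> float:
    """Penalty for fragment pairs closer than the SSE type-pair minimum,
    weighted by the interaction weight."""
    total = 0.0
    for p in features.packing_contacts(model):
        key = p.type_pair if p.type_pair in params.sse_min_distance else "HS"
        d_min = params.sse_min_distance[key]
        pen = float(_ramp_penalty(p.distance, d_min, params.ramp_width))
        if pen > 0:
            weight = max(p.interaction_weight, 0.1)  # clashes never fully vanish
            total += weight * pen
    return total


def score_loop_closure(model: ProteinModel, params: ClashParams) -> float:
    """Steep penalty when consecutive SSE ends are too far to bridge.

    The maximal bridgeable distance for an ``n``-residue loop is
    ``slope * n + intercept``; the excess enters a power-law ramp.
    """
    total = 0.0
    for n_loop, _, d_cn in features.loop_features(model):
        d_max = params.loop_closure_slope * max(n_loop, 0) + params.loop_closure_intercept
        if d_cn > d_max:
            total += (d_cn - d_max) ** params.loop_closure_exponent
    return total


# ---------------------------------------------------------------------------
# fitting of penalty parameters from a model database


def fit_aa_min_distances(models, resolution: float = 0.05, min_count: int = 2,
                         max_distance: float = 20.0,
                         default: float = 2.5) -> np.ndarray:
    """Shortest allowed distance per amino-acid type pair.

    All pair distances (sequence separation >= 3) are binned at
    ``resolution``; the lower edge of the first bin with at least
    ``min_count`` counts is the minimum permitted distance.  Unobserved pairs
    fall back to ``default``.
    """
    nbins = int(round(max_distance / resolution))
    counts = np.zeros((20, 20, nbins))
    for model in models:
        anchors, seq, chain, aa = features.model_arrays(model)
        n = len(seq)
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, k=1)
        mask = features._pair_mask(seq, chain, features.NC_MIN_SEQ_SEP)[iu, ju]
        iu, ju = iu[mask], ju[mask]
        dist = np.linalg.norm(anchors[iu] - anchors[ju], axis=1)
        inside = dist < max_distance
        idx = (dist[inside] / resolution).astype(int)
        a, b = aa[iu[inside]], aa[ju[inside]]
        np.add.at(counts, (a, b, idx), 1.0)
        np.add.at(counts, (b, a, idx), 1.0)
    out = np.full((20, 20), default)
    for i in range(20):
        for j in range(20):
            hits = np.nonzero(counts[i, j] >= min_count)[0]
            if len(hits):
                out[i, j] = hits[0] * resolution
    return np.minimum(out, out.T)


def fit_loop_closure(samples, percentile: float = 95.0,
                     max_loop: int = 20) -> tuple[float, float]:
    """Linear fit of the near-maximal end-to-end distance per loop length.

    ``samples`` is an iterable of ``(loop_length, distance)``; for each length
    between 1 and ``max_loop`` the given percentile of the distances is taken
    and a least-squares line fitted through the points.
    """
    per_length: dict[int, list[float]] = {}
    for n_loop, dist in samples:
        if 1 <= n_loop <= max_loop:
            per_length.setdefault(int(n_loop), []).append(float(dist))
    xs, ys = [], []
    for n_loop, values in sorted(per_length.items()):
        xs.append(n_loop)
        ys.append(float(np.percentile(values, percentile)))
    if len(xs) < 2:
        raise ValueError("need loop samples for at least two lengths")
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# all terms together


def score_all(model: ProteinModel, tables: TableSet,
              clash_params: ClashParams,
              predictions: dict | None = None,
              ss_params: SSAgreementParams | None = None) -> dict:
    """All twelve term values for one model.

    ``predictions`` maps a method name (``jufo``/``psipred``) to a
    ``{seq_id: (pC, pH, pE)}`` table; methods without predictions score 0.
    """
    predictions = predictions or {}
    contacts = score_sse_contacts(model, tables.packing)
    scores = {
        "aa_clash": score_aa_clash(model, clash_params),
        "aa_distance": score_aa_pair(model, tables.pair),
        "aa_neighbor": score_environment(model, tables.environment),
        "contact_order": score_contact_order(model, tables.contact_order),
        "loop_length": score_loop_length(model, tables.loop),
        "loop_closure": score_loop_closure(model, clash_params),
        "radius_of_gyration": score_radius_gyration(model, tables.radius_of_gyration),
        "sse_clash": score_sse_clash(model, clash_params),
        "sse_packing": contacts["sse_packing"],
        "strand_pairing": contacts["strand_pairing"],
    }
    for method in ("jufo", "psipred"):
        key = f"ss_{method}"
        if method in predictions:
            scores[key] = score_ss_agreement(
                model, predictions[method], method, ss_params
            )
        else:
            scores[key] = 0.0
    return scores
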