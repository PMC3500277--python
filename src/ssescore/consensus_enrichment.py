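"""Consensus scoring, enrichment statistics and weight optimization.

The consensus score is a linear combination of the twelve term scores.
Enrichment measures how strongly a score concentrates native-like models in
the best-scored fraction; weights are optimized by Metropolis simulated
annealing to maximize the summed square-root enrichment over balanced
cross-validation subsets.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy_terms import TERM_NAMES

#: consensus weight set (defaults of the optimized scoring function)
DEFAULT_WEIGHTS = {
    "aa_distance": 0.35,
    "aa_neighbor": 50.0,
    "loop_length": 10.0,
    "radius_of_gyration": 5.0,
    "loop_closure": 500.0,
    "aa_clash": 500.0,
    "sse_clash": 500.0,
    "sse_packing": 8.0,
    "strand_pairing": 20.0,
    "contact_order": 0.5,
    "ss_jufo": 5.0,
    "ss_psipred": 20.0,
}


@dataclass
class WeightSet:
    """Non-negative weight per scoring term."""

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self):
        for name in TERM_NAMES:
            self.weights.setdefault(name, 0.0)
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def as_array(self, order=TERM_NAMES) -> np.ndarray:
        return np.array([self.weights[n] for n in order])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.weights, indent=1))

    @classmethod
    def from_json(cls, path) -> "WeightSet":
        return cls(json.loads(Path(path).read_text()))


def weighted_sum(term_scores: dict, weights: WeightSet) -> float:
    """Linear consensus energy: sum of weight * term score."""
    return float(sum(weights[name] * value for name, value in term_scores.items()))


def rmsd100(rmsd: float, n_residues: int) -> float:
    """RMSD normalized to a 100-residue reference length."""
    if rmsd < 0 or n_residues <= 0:
        raise ValueError("rmsd must be >= 0 and n_residues positive")
    return rmsd / (1.0 + math.log(math.sqrt(n_residues / 100.0)))


def enrichment(scores, labels, fraction: float = 0.1) -> float:
    """Ratio of the positive rate in the best-scored fraction to the base rate.

    Lower score is better; ties are broken by stable input order.  With a 10%
    positive base rate the maximal attainable value is 10.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(scores)
    if n == 0 or len(labels) != n:
        raise ValueError("scores and labels must be equal-length and non-empty")
    positives = int(labels.sum())
    if positives == 0:
        raise ValueError("no positive models in the set")
    n_top = math.ceil(fraction * n)
    order = np.argsort(scores, kind="stable")
    tp = int(labels[order[:n_top]].sum())
    return (tp / n_top) / (positives / n)


def build_balanced_subsets(ids, labels, seed: int, n_subsets: int = 10,
                           target_fraction: float = 0.1):
    """Ten subsets at a 1:9 positive:negative ratio.

    The class over-represented relative to the target ratio is partitioned
    into ``n_subsets`` equal parts without reuse; members of the
    under-represented class are drawn randomly (without replacement inside a
    subset) to complete each subset.  Deterministic under ``seed``.
    """
    ids = list(ids)
    labels = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(labels)[0]
    neg_idx = np.nonzero(~labels)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes required")
    ratio = target_fraction / (1.0 - target_fraction)
    subsets = []
    if len(pos_idx) <= ratio * len(neg_idx):
        # negatives over-represented: partition them
        neg_perm = rng.permutation(neg_idx)
        per = len(neg_idx) // n_subsets
        n_pos = max(1, round(per * ratio))
        for k in range(n_subsets):
            part = neg_perm[k * per:(k + 1) * per]
            fill = rng.choice(pos_idx, size=min(n_pos, len(pos_idx)), replace=False)
            subsets.append(np.concatenate([fill, part]))
    else:
        pos_perm = rng.permutation(pos_idx)
        per = len(pos_idx) // n_subsets
        n_neg = max(1, round(per / ratio))
        for k in range(n_subsets):
            part = pos_perm[k * per:(k + 1) * per]
            fill = rng.choice(neg_idx, size=min(n_neg, len(neg_idx)), replace=False)
            subsets.append(np.concatenate([part, fill]))
    return [np.sort(s) for s in subsets]


@dataclass
class EnrichmentResult:
    """Cross-validated enrichment of one score over balanced subsets."""

    enrichments: list[float]
    fraction: float = 0.1

    @property
    def mean(self) -> float:
        return float(np.mean(self.enrichments))

    @property
    def sd(self) -> float:
        return float(np.std(self.enrichments, ddof=1))

    @property
    def z_score(self) -> float:
        sd = self.sd
        return float("inf") if sd == 0 else (self.mean - 1.0) / sd

    @property
    def significant(self) -> bool:
        return self.z_score > 1.0


def subset_enrichment(scores, labels, subsets,
                      fraction: float = 0.1) -> EnrichmentResult:
    """Enrichment of a score evaluated on each balanced subset."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    values = [enrichment(scores[s], labels[s], fraction) for s in subsets]
    return EnrichmentResult(values, fraction)


def _objective(weights: np.ndarray, sets, fraction: float) -> float:
    """Sum over sets of sqrt(enrichment of the weighted consensus score)."""
    total = 0.0
    for X, labels in sets:
        consensus = X @ weights
        total += math.sqrt(enrichment(consensus, labels, fraction))
    return total


def optimize_weights(sets, seed: int, fraction: float = 0.1,
                     max_iterations: int = 10_000,
                     patience: int = 250,
                     step_fraction: float = 0.1,
                     t_decay: float = 0.999,
                     t_start: float | None = None) -> tuple[np.ndarray, float]:
    """Metropolis simulated-annealing optimization of the consensus weights.

    ``sets`` is a list of ``(score_matrix, labels)`` pairs where the matrix
    has one column per term.  Start weights are the inverse standard
    deviation of each column pooled over all sets (zero-variance columns get
    weight 0).  Each step perturbs two randomly chosen weights by +/-10% of
    their start value, flooring at zero.  Returns ``(best_weights,
    best_objective)``; reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    X_all = np.vstack([X for X, _ in sets])
    sd = X_all.std(axis=0)
    zero_var = sd == 0
    if np.any(zero_var):
        warnings.warn("zero-variance score columns: start weight set to 0")
    start = np.where(zero_var, 0.0, 1.0 / np.where(zero_var, 1.0, sd))
    step = step_fraction * np.where(start > 0, start, 1.0)
    n_terms = X_all.shape[1]

    current = start.copy()
    current_obj = _objective(current, sets, fraction)
    best = current.copy()
    best_obj = current_obj

    if t_start is None:
        # calibrate so a median-size worsening move is accepted ~50% early on
        probes = []
        for _ in range(20):
            trial = current.copy()
            for idx in rng.choice(n_terms, size=2, replace=False):
                trial[idx] = max(0.0, trial[idx] + rng.choice([-1.0, 1.0]) * step[idx])
            probes.append(abs(_objective(trial, sets, fraction) - current_obj))
        scale = float(np.median(probes))
        t_start = scale / math.log(2.0) if scale > 0 else 1e-3
    temperature = t_start

    stale = 0
    for _ in range(max_iterations):
        trial = current.copy()
        for idx in rng.choice(n_terms, size=2, replace=False):
            trial[idx] = max(0.0, trial[idx] + rng.choice([-1.0, 1.0]) * step[idx])
        trial_obj = _objective(trial, sets, fraction)
        delta = trial_obj - current_obj
        if delta >= 0 or rng.random() < math.exp(delta / max(temperature, 1e-12)):
            current, current_obj = trial, trial_obj
        if current_obj > best_obj + 1e-12:
            best, best_obj = current.copy(), current_obj
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
        temperature *= t_decay
    return best, best_obj
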