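"""Histogram -> energy conversion and per-term training.

Feature counts collected over a training set are converted into binned energy
functions through the inverse Boltzmann relation

    E(f) = -ln(p(f) / p_bg(f))

with RT fixed to one energy unit.  Under-populated bins receive a constant
repulsive energy (``REPULSIVE_ENERGY``) instead of an arbitrary pseudo-count
energy.  Evaluation interpolates linearly (1D) or bilinearly (2D) between bin
centers so every potential is continuous.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import features
from .model_io import AA3, ProteinModel

#: constant repulsive energy for under-populated bins (energy units)
REPULSIVE_ENERGY = 18.0

#: raw-count thresholds below which a bin is treated as unobserved
ENV_MIN_RAW_COUNT = 2  # empty or single-count neighbor-count bins
PAIR_MIN_RAW_COUNT = 5  # pair-distance bins with fewer than five counts

STAT_TERMS = (
    "aa_environment",
    "aa_distance",
    "loop_length",
    "strand_pairing",
    "sse_packing",
    "contact_order",
    "radius_of_gyration",
)


def pair_key(aa_a: str, aa_b: str) -> str:
    """Canonical unordered amino-acid pair key, e.g. ``"ILE-LEU"``."""
    a, b = sorted((aa_a, aa_b))
    return f"{a}-{b}"


@dataclass
class Histogram:
    """Weighted counts on a 1D or 2D binning.

    ``raw`` carries unweighted observation counts for pseudo-count decisions;
    it defaults to ``counts`` when the two coincide.
    """

    edges: tuple[np.ndarray, ...]
    counts: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self):
        self.edges = tuple(np.asarray(e, float) for e in self.edges)
        self.counts = np.asarray(self.counts, float)
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expected = tuple(len(e) - 1 for e in self.edges)
        if self.counts.shape != expected:
            raise ValueError("counts shape does not match edges")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, float)

    @property
    def dimensionality(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


@dataclass
class EnergyTable:
    """Binned energy function with interpolation and edge policies.

    ``out_low`` / ``out_high`` control behaviour beyond the outermost bin
    centers on each axis: ``"clamp"`` holds the edge value, ``"zero"``
    interpolates to zero over one virtual bin.  A ``periodic`` axis (used for
    twist angles over (-180, 180]) wraps around instead.
    """

    edges: tuple[np.ndarray, ...]
    energies: np.ndarray
    out_low: tuple[str, ...] = ()
    out_high: tuple[str, ...] = ()
    periodic: tuple[bool, ...] = ()

    def __post_init__(self):
        self.edges = tuple(np.asarray(e, float) for e in self.edges)
        self.energies = np.asarray(self.energies, float)
        ndim = len(self.edges)
        if not self.out_low:
            self.out_low = ("clamp",) * ndim
        if not self.out_high:
            self.out_high = ("clamp",) * ndim
        if not self.periodic:
            self.periodic = (False,) * ndim
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")
        self._grid = None

    @property
    def dimensionality(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def _extended(self):
        """Per-axis (centers, index-map) extension implementing the policies."""
        if self._grid is not None:
            return self._grid
        axes = []
        energies = self.energies
        for ax in range(len(self.edges)):
            c = self.centers[ax]
            w_lo = c[1] - c[0] if len(c) > 1 else self.edges[ax][1] - self.edges[ax][0]
            ext_c = list(c)
            take = list(range(len(c)))
            pad_lo = pad_hi = None
            if self.periodic[ax]:
                period = self.edges[ax][-1] - self.edges[ax][0]
                ext_c = [c[-1] - period] + ext_c + [c[0] + period]
                take = [len(c) - 1] + take + [0]
            else:
                if self.out_low[ax] == "zero":
                    ext_c = [c[0] - w_lo] + ext_c
                    take = [-1] + take
                    pad_lo = True
                if self.out_high[ax] == "zero":
                    ext_c = ext_c + [c[-1] + w_lo]
                    take = take + [-1]
                    pad_hi = True
            axes.append((np.array(ext_c), take))
        ext_e = energies
        for ax, (ext_c, take) in enumerate(axes):
            slices = []
            for idx in take:
                if idx == -1:
                    shape = list(ext_e.shape)
                    shape[ax] = 1
                    slices.append(np.zeros(shape))
                else:
                    slices.append(np.take(ext_e, [idx], axis=ax))
            ext_e = np.concatenate(slices, axis=ax)
        self._grid = (tuple(a[0] for a in axes), ext_e)
        return self._grid

    def evaluate(self, *coords):
        """Interpolated energy at scalar or array coordinates."""
        (centers, energies) = self._extended()
        coords = [np.asarray(c, float) for c in coords]
        if len(coords) != len(self.edges):
            raise ValueError("coordinate count does not match dimensionality")
        for c in coords:
            if np.any(~np.isfinite(c)):
                raise ValueError("NaN/inf input to energy table evaluation")
        scalar = all(c.ndim == 0 for c in coords)
        if self.dimensionality == 1:
            x = np.atleast_1d(coords[0])
            out = np.interp(x, centers[0], energies)
            return float(out[0]) if scalar else out
        x = np.atleast_1d(coords[0]).astype(float)
        y = np.atleast_1d(coords[1]).astype(float)
        x, y = np.broadcast_arrays(x, y)
        if self.periodic[1]:
            period = self.edges[1][-1] - self.edges[1][0]
            lo = centers[1][0]
            y = (y - lo) % period + lo
        xq = np.clip(x, centers[0][0], centers[0][-1])
        yq = np.clip(y, centers[1][0], centers[1][-1])
        ix = np.clip(np.searchsorted(centers[0], xq) - 1, 0, len(centers[0]) - 2)
        iy = np.clip(np.searchsorted(centers[1], yq) - 1, 0, len(centers[1]) - 2)
        x0, x1 = centers[0][ix], centers[0][ix + 1]
        y0, y1 = centers[1][iy], centers[1][iy + 1]
        tx = np.where(x1 > x0, (xq - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
        ty = np.where(y1 > y0, (yq - y0) / np.where(y1 > y0, y1 - y0, 1.0), 0.0)
        e00 = energies[ix, iy]
        e01 = energies[ix, iy + 1]
        e10 = energies[ix + 1, iy]
        e11 = energies[ix + 1, iy + 1]
        out = (
            e00 * (1 - tx) * (1 - ty)
            + e10 * tx * (1 - ty)
            + e01 * (1 - tx) * ty
            + e11 * tx * ty
        )
        return float(out.flat[0]) if scalar else out

    def to_dict(self) -> dict:
        return {
            "edges": [e.tolist() for e in self.edges],
            "energies": np.round(self.energies, 6).tolist(),
            "out_low": list(self.out_low),
            "out_high": list(self.out_high),
            "periodic": list(self.periodic),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyTable":
        return cls(
            edges=tuple(np.array(e) for e in d["edges"]),
            energies=np.array(d["energies"]),
            out_low=tuple(d["out_low"]),
            out_high=tuple(d["out_high"]),
            periodic=tuple(d["periodic"]),
        )


def energy_from_counts(
    hist: Histogram,
    background: np.ndarray,
    min_raw_count: float = 1,
    repulsive: float = REPULSIVE_ENERGY,
    out_low: tuple[str, ...] = (),
    out_high: tuple[str, ...] = (),
    periodic: tuple[bool, ...] = (),
) -> EnergyTable:
    """Inverse-Boltzmann conversion of a histogram against a background.

    Bins whose raw count is below ``min_raw_count`` receive the constant
    ``repulsive`` energy.  ``background`` must be a probability table of the
    histogram's shape (it is renormalized defensively).
    """
    background = np.asarray(background, float)
    if background.shape != hist.counts.shape:
        raise ValueError("background shape does not match histogram")
    if np.any(background < 0):
        raise ValueError("background must be non-negative")
    total_bg = background.sum()
    if total_bg <= 0:
        raise ValueError("background sums to zero")
    p_bg = background / total_bg
    raw = hist.raw if hist.raw is not None else hist.counts
    total = hist.counts.sum()
    if total <= 0:
        warnings.warn("all-zero histogram: returning all-repulsive table")
        energies = np.full(hist.counts.shape, repulsive)
    else:
        p = hist.counts / total
        if np.any((p_bg == 0) & (p > 0)):
            raise ValueError("background is zero where counts are nonzero")
        valid = (raw >= min_raw_count) & (p > 0) & (p_bg > 0)
        energies = np.full(hist.counts.shape, repulsive)
        energies[valid] = -np.log(p[valid] / p_bg[valid])
    return EnergyTable(hist.edges, energies, out_low, out_high, periodic)


@dataclass
class TrainingConfig:
    """Binning and pseudo-count configuration for all statistical terms."""

    env_nc_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 25.0, 1.0))
    pair_d_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 21.0, 1.0))
    loop_n_edges: np.ndarray = field(default_factory=lambda: np.arange(-0.5, 25.0, 1.0))
    loop_d_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 41.0, 1.0))
    loop_pseudo: float = 1.0  # pseudo count divided by d^2 fills empty loop bins
    pairing_d_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 20.5, 0.5))
    packing_d_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 21.0, 1.0))
    theta_edges: np.ndarray = field(default_factory=lambda: np.arange(-180.0, 181.0, 15.0))
    co_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 5.05, 0.1))
    rg_edges: np.ndarray = field(default_factory=lambda: np.arange(0.0, 6.05, 0.1))


def _collect_environment(models, cfg: TrainingConfig):
    edges = cfg.env_nc_edges
    counts = {aa: np.zeros(len(edges) - 1) for aa in AA3}
    for model in models:
        nc = features.neighbor_counts(model)
        for res, value in zip(model.residues, nc):
            idx = np.clip(np.searchsorted(edges, value, side="right") - 1,
                          0, len(edges) - 2)
            counts[res.aa_type][idx] += 1.0
    return counts


def build_environment_tables(models, cfg: TrainingConfig) -> dict:
    """Per-amino-acid neighbor-count potentials.

    The background is the normalized sum of all per-type normalized
    neighbor-count distributions.
    """
    counts = _collect_environment(models, cfg)
    background = np.zeros(len(cfg.env_nc_edges) - 1)
    for aa in AA3:
        total = counts[aa].sum()
        if total > 0:
            background += counts[aa] / total
    if background.sum() == 0:
        background[:] = 1.0
    tables = {}
    for aa in AA3:
        hist = Histogram((cfg.env_nc_edges,), counts[aa])
        tables[aa] = energy_from_counts(
            hist, background, min_raw_count=ENV_MIN_RAW_COUNT
        )
    return tables


def build_pair_tables(models, cfg: TrainingConfig) -> dict:
    """Amino-acid pair distance potentials for all 210 unordered type pairs.

    Background for pair (a, b) at distance d: the frequency of seeing a or b
    with any other amino acid at distance d.
    """
    edges = cfg.pair_d_edges
    nbins = len(edges) - 1
    counts = np.zeros((20, 20, nbins))
    for model in models:
        ai, aj, dist = features.pair_distance_features(model)
        inside = dist < edges[-1]
        ai, aj, dist = ai[inside], aj[inside], dist[inside]
        idx = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, nbins - 1)
        np.add.at(counts, (ai, aj, idx), 1.0)
        np.add.at(counts, (aj, ai, idx), 1.0)
    marginal = counts.sum(axis=1)  # counts of type a with any partner at d
    tables = {}
    for i, aa_a in enumerate(AA3):
        for j in range(i, 20):
            aa_b = AA3[j]
            pair_counts = counts[i, j]
            hist = Histogram((edges,), pair_counts)
            background = marginal[i] + marginal[j]
            if background.sum() == 0:
                background = np.ones(nbins)
            with warnings.catch_warnings():
                if pair_counts.sum() == 0:  # unobserved pair: expected
                    warnings.simplefilter("ignore")
                tables[pair_key(aa_a, aa_b)] = energy_from_counts(
                    hist, background, min_raw_count=PAIR_MIN_RAW_COUNT,
                    out_low=("clamp",), out_high=("zero",),
                )
    return tables


def build_loop_table(models, cfg: TrainingConfig) -> EnergyTable:
    """Loop (sequence distance, axis-tip Euclidean distance) potential.

    Empty bins are filled with a pseudo count proportional to ``1/d^2`` so the
    energy of bridging a long distance grows steadily with ``ln(d^2)``.
    """
    n_edges, d_edges = cfg.loop_n_edges, cfg.loop_d_edges
    counts = np.zeros((len(n_edges) - 1, len(d_edges) - 1))
    raw = np.zeros_like(counts)
    for model in models:
        for n_loop, tip_d, _ in features.loop_features(model):
            if not (n_edges[0] <= n_loop < n_edges[-1]) or tip_d >= d_edges[-1]:
                continue
            i = np.searchsorted(n_edges, n_loop, side="right") - 1
            j = np.searchsorted(d_edges, tip_d, side="right") - 1
            counts[i, j] += 1.0
            raw[i, j] += 1.0
    d_centers = 0.5 * (d_edges[1:] + d_edges[:-1])
    pseudo = cfg.loop_pseudo / np.maximum(d_centers, 0.5) ** 2
    counts = counts + pseudo[None, :]
    hist = Histogram((n_edges, d_edges), counts, raw=raw + 1.0)
    background = np.ones_like(counts)
    return energy_from_counts(
        hist, background, min_raw_count=0,
        out_low=("clamp", "clamp"), out_high=("clamp", "clamp"),
    )


_PACK_KEYS = ("HH", "HS", "SS_PAIR", "SS_SAND")


def _collect_packing(models, cfg: TrainingConfig):
    """Weighted (distance, theta) histograms per packing table."""
    hists = {}
    for key in _PACK_KEYS:
        d_edges = cfg.pairing_d_edges if key == "SS_PAIR" else cfg.packing_d_edges
        shape = (len(d_edges) - 1, len(cfg.theta_edges) - 1)
        hists[key] = [d_edges, np.zeros(shape), np.zeros(shape)]
    t_edges = cfg.theta_edges

    def _deposit(key, d, theta, weight):
        if weight <= 0:
            return
        d_edges, counts, raw = hists[key]
        if d >= d_edges[-1]:
            return
        i = np.clip(np.searchsorted(d_edges, d, side="right") - 1, 0,
                    counts.shape[0] - 1)
        j = np.clip(np.searchsorted(t_edges, theta, side="right") - 1, 0,
                    counts.shape[1] - 1)
        counts[i, j] += weight
        raw[i, j] += 1.0

    for model in models:
        for p in features.packing_contacts(model):
            if p.type_pair == "SS":
                _deposit("SS_PAIR", p.distance, p.theta, p.weight_pairing)
                _deposit("SS_SAND", p.distance, p.theta, p.weight_sandwich)
            else:
                _deposit(p.type_pair, p.distance, p.theta, p.interaction_weight)
    return hists


def build_packing_tables(models, cfg: TrainingConfig) -> dict:
    """(distance, twist) potentials for HH, HS, SS_PAIR and SS_SAND contacts.

    Interaction weights serve as the counts; the background is proportional
    to the distance (the chance of finding a partner SSE grows linearly with
    separation).  Empty bins are repulsive.
    """
    hists = _collect_packing(models, cfg)
    tables = {}
    for key, (d_edges, counts, raw) in hists.items():
        d_centers = 0.5 * (d_edges[1:] + d_edges[:-1])
        background = np.broadcast_to(
            np.maximum(d_centers, 1e-3)[:, None], counts.shape
        ).copy()
        hist = Histogram((d_edges, cfg.theta_edges), counts, raw=raw)
        tables[key] = energy_from_counts(
            hist, background, min_raw_count=1,
            out_low=("clamp", "clamp"), out_high=("zero", "clamp"),
            periodic=(False, True),
        )
    return tables


def _scalar_table(values, edges, min_raw_count=1) -> EnergyTable:
    counts = np.zeros(len(edges) - 1)
    for v in values:
        if edges[0] <= v < edges[-1]:
            counts[np.searchsorted(edges, v, side="right") - 1] += 1.0
    hist = Histogram((edges,), counts)
    background = np.ones_like(counts)
    return energy_from_counts(hist, background, min_raw_count=min_raw_count)


def build_contact_order_table(models, cfg: TrainingConfig) -> EnergyTable:
    """Directly collected histogram of CO^2/n with a uniform background."""
    return _scalar_table(
        [features.contact_order_norm(m) for m in models], cfg.co_edges
    )


def build_radius_of_gyration_table(models, cfg: TrainingConfig) -> EnergyTable:
    """Directly collected histogram of r^2/n with a uniform background."""
    return _scalar_table(
        [features.radius_of_gyration_norm(m) for m in models], cfg.rg_edges
    )


@dataclass
class TableSet:
    """All trained energy tables of the scoring function."""

    environment: dict
    pair: dict
    loop: EnergyTable
    packing: dict  # keys HH, HS, SS_PAIR, SS_SAND
    contact_order: EnergyTable
    radius_of_gyration: EnergyTable

    def to_json(self, path) -> None:
        payload = {
            "environment": {k: v.to_dict() for k, v in self.environment.items()},
            "pair": {k: v.to_dict() for k, v in self.pair.items()},
            "loop": self.loop.to_dict(),
            "packing": {k: v.to_dict() for k, v in self.packing.items()},
            "contact_order": self.contact_order.to_dict(),
            "radius_of_gyration": self.radius_of_gyration.to_dict(),
            "version": 1,
        }
        Path(path).write_text(json.dumps(payload, separators=(",", ":")))

    @classmethod
    def from_json(cls, path) -> "TableSet":
        d = json.loads(Path(path).read_text())
        return cls(
            environment={k: EnergyTable.from_dict(v)
                         for k, v in d["environment"].items()},
            pair={k: EnergyTable.from_dict(v) for k, v in d["pair"].items()},
            loop=EnergyTable.from_dict(d["loop"]),
            packing={k: EnergyTable.from_dict(v) for k, v in d["packing"].items()},
            contact_order=EnergyTable.from_dict(d["contact_order"]),
            radius_of_gyration=EnergyTable.from_dict(d["radius_of_gyration"]),
        )


def build_term_statistics(models: list[ProteinModel], term: str,
                          cfg: TrainingConfig | None = None):
    """Train the table (or table set) for one named statistical term."""
    cfg = cfg or TrainingConfig()
    builders = {
        "aa_environment": build_environment_tables,
        "aa_distance": build_pair_tables,
        "loop_length": build_loop_table,
        "strand_pairing": lambda m, c: build_packing_tables(m, c)["SS_PAIR"],
        "sse_packing": build_packing_tables,
        "contact_order": build_contact_order_table,
        "radius_of_gyration": build_radius_of_gyration_table,
    }
    if term not in builders:
        raise ValueError(f"unknown statistical term {term!r}")
    return builders[term](models, cfg)


def train_tables(models: list[ProteinModel],
                 cfg: TrainingConfig | None = None) -> TableSet:
    """Train the full table set on a model database."""
    cfg = cfg or TrainingConfig()
    packing = build_packing_tables(models, cfg)
    return TableSet(
        environment=build_environment_tables(models, cfg),
        pair=build_pair_tables(models, cfg),
        loop=build_loop_table(models, cfg),
        packing=packing,
        contact_order=build_contact_order_table(models, cfg),
        radius_of_gyration=build_radius_of_gyration_table(models, cfg),
    )


def default_tables() -> TableSet:
    """The bundled fixture-trained table set."""
    with resources.as_file(
        resources.files("ssescore.data") / "fixture_tables.json"
    ) as path:
        return TableSet.from_json(path)
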