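"""Reduced protein models: PDB parsing, side-chain anchors, SSE fragments.

A model consists only of its secondary structure elements (SSEs).  Every
residue carries a single side-chain anchor point: the C-beta atom, or the
H-alpha2 atom for glycine.  Residues with neither are reconstructed from the
backbone with ideal tetrahedral geometry, or skipped with a warning.

Each SSE is decomposed into overlapping windows of 5 (helix) / 3 (strand)
residues; superimposing an ideal template onto each window yields an oriented
main-axis line segment per fragment.  The effective segment used for packing
geometry is the full segment trimmed by 2 A at each end.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from . import ideal
from ._geometry import kabsch, unit

HELIX = ideal.HELIX
STRAND = ideal.STRAND

#: end trim applied to each fragment main axis before packing geometry (A)
AXIS_END_TRIM = 2.0

AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA1 = "ARNDCQEGHILKMFPSTWYV"
AA3_TO_1 = dict(zip(AA3, AA1))
AA1_TO_3 = dict(zip(AA1, AA3))
AA_INDEX = {a: i for i, a in enumerate(AA3)}

# ideal tetrahedral C-beta reconstruction parameters
CB_BOND_LENGTH = 1.53
CB_ANGLE_DEG = 110.5


@dataclass(frozen=True)
class AminoAcid:
    """One residue of the reduced model."""

    chain_id: str
    seq_id: int
    aa_type: str  # canonical three-letter code
    anchor: np.ndarray  # side-chain anchor point (A)
    backbone: dict[str, np.ndarray] | None = None  # N/CA/C coordinates if known

    def __post_init__(self):
        if self.aa_type not in AA_INDEX:
            raise ValueError(f"non-canonical amino acid type {self.aa_type!r}")
        anchor = np.asarray(self.anchor, dtype=float)
        if anchor.shape != (3,) or not np.all(np.isfinite(anchor)):
            raise ValueError("anchor must be a finite 3D coordinate")
        object.__setattr__(self, "anchor", anchor)

    @property
    def ca(self) -> np.ndarray:
        """C-alpha coordinate; falls back to the anchor when absent."""
        if self.backbone and "CA" in self.backbone:
            return self.backbone["CA"]
        return self.anchor

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AminoAcid":
        bb = None
        if self.backbone is not None:
            bb = {k: v @ R.T + t for k, v in self.backbone.items()}
        return replace(self, anchor=self.anchor @ R.T + t, backbone=bb)


@dataclass(frozen=True)
class Fragment:
    """Oriented main-axis window of an SSE.

    ``axis`` points along the sequence direction (N- to C-terminus).  The full
    segment spans the projections of the window residues onto the fitted axis;
    the effective segment is shortened by ``AXIS_END_TRIM`` at each end.
    ``face`` is the unit vector from the axis towards the central residue's
    anchor (defined for strands; ``None`` for helices).
    """

    sse_type: str
    center_index: int
    origin: np.ndarray
    axis: np.ndarray
    full_segment: np.ndarray  # (2, 3) endpoints, sequence order
    effective_segment: np.ndarray  # (2, 3) endpoints
    face: np.ndarray | None = None

    @property
    def full_length(self) -> float:
        return float(np.linalg.norm(self.full_segment[1] - self.full_segment[0]))

    @property
    def effective_length(self) -> float:
        return float(
            np.linalg.norm(self.effective_segment[1] - self.effective_segment[0])
        )


class SSE:
    """A helix or strand: contiguous residues plus their axis fragments."""

    def __init__(self, sse_type: str, residues: list[AminoAcid]):
        if sse_type not in (HELIX, STRAND):
            raise ValueError(f"unknown SSE type {sse_type!r}")
        if not residues:
            raise ValueError("SSE requires at least one residue")
        chains = {r.chain_id for r in residues}
        if len(chains) > 1:
            raise ValueError("SSE residues must share one chain")
        seq = [r.seq_id for r in residues]
        if any(b - a != 1 for a, b in zip(seq, seq[1:])):
            raise ValueError("SSE residues must be contiguous in seq_id")
        self.sse_type = sse_type
        self.residues = list(residues)
        self._fragments: list[Fragment] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain_id

    @property
    def first_seq(self) -> int:
        return self.residues[0].seq_id

    @property
    def last_seq(self) -> int:
        return self.residues[-1].seq_id

    @property
    def include_in_packing(self) -> bool:
        """Short SSEs are excluded from packing statistics and scores."""
        return len(self.residues) >= ideal.MIN_PACKING_LENGTH[self.sse_type]

    @property
    def fragments(self) -> list[Fragment]:
        if self._fragments is None:
            self._fragments = fragment_decompose(self)
        return self._fragments

    def anchors(self) -> np.ndarray:
        return np.array([r.anchor for r in self.residues])

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SSE":
        return SSE(self.sse_type, [r.transformed(R, t) for r in self.residues])

    def copy(self) -> "SSE":
        return SSE(self.sse_type, list(self.residues))


class ProteinModel:
    """SSE-only reduced structure.

    ``n_residues`` is the full sequence length including (implicit) loop
    residues.  When not given it defaults to the summed per-chain seq_id span.
    """

    def __init__(self, sses: list[SSE], n_residues: int | None = None,
                 name: str = "model"):
        sses = sorted(sses, key=lambda s: (s.chain_id, s.first_seq))
        for a, b in zip(sses, sses[1:]):
            if a.chain_id == b.chain_id and b.first_seq <= a.last_seq:
                raise ValueError("SSEs overlap in sequence")
        self.sses = sses
        self.name = name
        if n_residues is None:
            n_residues = 0
            for chain in self.chains:
                seqs = [r.seq_id for s in sses if s.chain_id == chain
                        for r in s.residues]
                if seqs:
                    n_residues += max(seqs) - min(seqs) + 1
        n_sse = sum(len(s) for s in sses)
        if n_residues < n_sse:
            raise ValueError("n_residues smaller than number of SSE residues")
        self.n_residues = int(n_residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for s in self.sses:
            if s.chain_id not in seen:
                seen.append(s.chain_id)
        return seen

    @property
    def residues(self) -> list[AminoAcid]:
        return [r for s in self.sses for r in s.residues]

    def anchors(self) -> np.ndarray:
        res = self.residues
        if not res:
            return np.zeros((0, 3))
        return np.array([r.anchor for r in res])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ProteinModel":
        return ProteinModel([s.transformed(R, t) for s in self.sses],
                            n_residues=self.n_residues, name=self.name)

    def copy(self) -> "ProteinModel":
        return ProteinModel([s.copy() for s in self.sses],
                            n_residues=self.n_residues, name=self.name)


def reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position from backbone N/CA/C (tetrahedral geometry).

    The bond length is exactly ``CB_BOND_LENGTH`` and the N-CA-CB and C-CA-CB
    angles both equal ``CB_ANGLE_DEG`` (up to clamping for distorted input).
    """
    u1 = unit(np.asarray(n, float) - ca)
    u2 = unit(np.asarray(c, float) - ca)
    bisector = unit(u1 + u2)
    normal = unit(np.cross(u2, u1))
    cos_half = float(np.clip(u1 @ bisector, 1e-6, 1.0))
    cos_phi = np.clip(-np.cos(np.radians(CB_ANGLE_DEG)) / cos_half, -1.0, 1.0)
    sin_phi = np.sqrt(max(0.0, 1.0 - cos_phi ** 2))
    direction = -cos_phi * bisector + sin_phi * normal
    return np.asarray(ca, float) + CB_BOND_LENGTH * direction


def _resolve_anchor(resname: str, atoms: dict[str, np.ndarray]) -> np.ndarray | None:
    if resname == "GLY":
        for name in ("HA2", "2HA", "HA3", "3HA"):
            if name in atoms:
                return atoms[name]
    elif "CB" in atoms:
        return atoms["CB"]
    if all(k in atoms for k in ("N", "CA", "C")):
        return reconstruct_cb(atoms["N"], atoms["CA"], atoms["C"])
    return None


def _parse_sse_records(path: Path) -> list[tuple[str, str, int, int]]:
    """HELIX/SHEET ranges from PDB header lines: (type, chain, first, last)."""
    ranges = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("HELIX"):
                ranges.append(
                    (HELIX, line[19].strip() or line[31].strip(),
                     int(line[21:25]), int(line[33:37]))
                )
            elif line.startswith("SHEET"):
                ranges.append(
                    (STRAND, line[21].strip(), int(line[22:26]), int(line[33:37]))
                )
    return ranges


def read_ss_assignment(path) -> dict[int, str]:
    """Two-column per-residue secondary structure file: ``seq_id  H|E|C``."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            state = parts[1].upper()
            if state not in "HEC":
                raise ValueError(f"invalid SS state {parts[1]!r}")
            out[int(parts[0])] = state
    return out


def _ranges_from_assignment(assignment: dict[int, str]) -> list[tuple[str, int, int]]:
    """Maximal runs of H / E over consecutive seq ids."""
    ranges = []
    for seq in sorted(assignment):
        state = assignment[seq]
        if state == "C":
            continue
        if ranges and ranges[-1][0] == state and ranges[-1][2] == seq - 1:
            ranges[-1] = (state, ranges[-1][1], seq)
        else:
            ranges.append((state, seq, seq))
    return ranges


def read_pdb(path, ss_assignment: dict[int, str] | None = None,
             name: str | None = None) -> ProteinModel:
    """Parse a PDB file into an SSE-only reduced model.

    SSE definitions come from an external per-residue assignment when given
    (takes precedence), otherwise from HELIX/SHEET records.  Residues outside
    SSEs contribute to ``n_residues`` but are not part of the model.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    model0 = next(iter(structure))
    residues: dict[tuple[str, int], AminoAcid] = {}
    spans: dict[str, list[int]] = {}
    for chain in model0:
        for res in chain:
            het, seq_id, icode = res.id
            if het.strip():
                continue
            resname = res.get_resname()
            if resname not in AA_INDEX:
                continue
            if icode.strip():
                raise ValueError(
                    f"insertion codes are not supported ({chain.id}{seq_id}{icode})"
                )
            atoms = {a.get_name(): a.get_coord().astype(float) for a in res}
            anchor = _resolve_anchor(resname, atoms)
            if anchor is None:
                warnings.warn(
                    f"residue {chain.id}{seq_id} {resname}: no anchor atom and "
                    "incomplete backbone; skipped"
                )
                continue
            backbone = {k: atoms[k] for k in ("N", "CA", "C", "O") if k in atoms}
            residues[(chain.id, seq_id)] = AminoAcid(
                chain.id, seq_id, resname, anchor, backbone or None
            )
            spans.setdefault(chain.id, []).append(seq_id)

    if ss_assignment is not None:
        default_chain = next(iter(spans), "A")
        ranges = [(t, default_chain, a, b)
                  for t, a, b in _ranges_from_assignment(ss_assignment)]
    else:
        ranges = _parse_sse_records(path)

    sses = []
    for sse_type, chain_id, first, last in ranges:
        run: list[AminoAcid] = []
        for seq in range(first, last + 1):
            res = residues.get((chain_id, seq))
            if res is None:
                if run:
                    sses.append(SSE(sse_type, run))
                    run = []
                continue
            run.append(res)
        if run:
            sses.append(SSE(sse_type, run))

    n_residues = sum(max(v) - min(v) + 1 for v in spans.values()) or None
    return ProteinModel(sses, n_residues=n_residues, name=name or path.stem)


def fragment_decompose(sse: SSE) -> list[Fragment]:
    """Overlapping oriented fragments of an SSE.

    Returns ``n - l + 1`` fragments for an SSE of ``n`` residues and fragment
    length ``l`` (5 helix / 3 strand), or an empty list for shorter SSEs.  Each
    axis is obtained by least-squares superposition of the ideal template onto
    the window's C-alpha coordinates.
    """
    length = ideal.FRAGMENT_LENGTH[sse.sse_type]
    n = len(sse.residues)
    if n < length:
        return []
    template = ideal.template_ca(sse.sse_type, length)
    ca = sse.ca_coords()
    frags = []
    for start in range(n - length + 1):
        window = ca[start:start + length]
        R, t = kabsch(template, window)
        axis = R @ np.array([0.0, 0.0, 1.0])
        if axis @ (window[-1] - window[0]) < 0:
            axis = -axis
        origin = window.mean(axis=0)
        proj = (window - origin) @ axis
        p0 = origin + proj.min() * axis
        p1 = origin + proj.max() * axis
        full = np.array([p0, p1])
        half_span = 0.5 * (proj.max() - proj.min())
        trim = min(AXIS_END_TRIM, half_span - 0.05)
        mid = 0.5 * (p0 + p1)
        eff = np.array([p0 + trim * axis, p1 - trim * axis])
        if np.linalg.norm(eff[1] - eff[0]) < 0.1:
            eff = np.array([mid - 0.05 * axis, mid + 0.05 * axis])
        face = None
        if sse.sse_type == STRAND:
            center = start + length // 2
            v = sse.residues[center].anchor - origin
            v = v - (v @ axis) * axis
            nv = np.linalg.norm(v)
            face = v / nv if nv > 1e-9 else _any_perpendicular(axis)
        frags.append(
            Fragment(sse.sse_type, start + length // 2, origin, axis, full, eff, face)
        )
    return frags


def _any_perpendicular(axis: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(axis, ref))


def read_ss2(path) -> dict[int, tuple[float, float, float]]:
    """PSIPRED ``.ss2``-style file -> ``{seq_id: (pC, pH, pE)}``."""
    out: dict[int, tuple[float, float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"malformed .ss2 line: {line!r}")
            out[int(parts[0])] = (float(parts[3]), float(parts[4]), float(parts[5]))
    return out


def write_ss2(path, rows: list[tuple[int, str, str, float, float, float]]) -> None:
    """Write ``(seq_id, aa1, state, pC, pH, pE)`` rows in .ss2 layout."""
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (ssescore synthetic)\n\n")
        for seq, aa, state, pc, ph, pe in rows:
            fh.write(f"{seq:4d} {aa} {state}  {pc:6.3f} {ph:6.3f} {pe:6.3f}\n")


def write_pdb(model: ProteinModel, path) -> None:
    """Write the reduced model as a PDB file with HELIX/SHEET records."""
    lines = []
    helix_no = sheet_no = 0
    for sse in model.sses:
        first, last = sse.residues[0], sse.residues[-1]
        if sse.sse_type == HELIX:
            helix_no += 1
            lines.append(
                f"HELIX  {helix_no:3d} {helix_no:3d} {first.aa_type:>3s} "
                f"{first.chain_id}{first.seq_id:5d}  {last.aa_type:>3s} "
                f"{last.chain_id}{last.seq_id:5d}  1{'':30s}"
            )
        else:
            sheet_no += 1
            lines.append(
                f"SHEET  {sheet_no:3d}   A 1 {first.aa_type:>3s} "
                f"{first.chain_id}{first.seq_id:4d}  {last.aa_type:>3s} "
                f"{last.chain_id}{last.seq_id:4d}  0"
            )
    serial = 0
    for sse in model.sses:
        for res in sse.residues:
            named = []
            if res.backbone:
                named.extend(
                    (k, res.backbone[k]) for k in ("N", "CA", "C") if k in res.backbone
                )
            anchor_name = "HA2" if res.aa_type == "GLY" else "CB"
            named.append((anchor_name, res.anchor))
            for atom_name, xyz in named:
                serial += 1
                element = atom_name[0]
                field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {field} {res.aa_type:>3s} "
                    f"{res.chain_id}{res.seq_id:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
                )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
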