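"""Cα-level structure model and the membrane coordinate frame.

All downstream geometry assumes coordinates in a membrane frame: an implicit
bilayer whose mid-plane is the set of points ``p`` with
``dot(normal, p) - z_offset = 0`` and whose ``normal`` points toward the
extracellular (EC) side.  Structures pre-oriented by the OPM convention
(membrane mid-plane at z = 0, EC side at z > 0) are covered by the default
frame; for anything else :func:`orient_fallback` builds a frame from the
transmembrane helix axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mappable to a parent standard letter
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}


class StructureError(Exception):
    """Base class for structure-model failures."""


class ParseError(StructureError):
    """The input file could not be parsed in the stated dialect."""


class EmptyStructureError(StructureError):
    """The parsed structure contains no residue with a Cα atom."""


class InsufficientDataError(StructureError):
    """Not enough geometric information for the requested operation."""


@dataclass(frozen=True)
class Residue:
    """One amino acid reduced to its Cα position.

    ``seq_number``/``insertion_code`` preserve author numbering; ``aa`` is a
    one-letter code with ``X`` for anything nonstandard.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str
    ca: np.ndarray

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.shape != (3,) or not np.all(np.isfinite(ca)):
            raise StructureError(
                f"residue {self.key}: Cα must be a finite 3-vector, got {self.ca!r}"
            )
        object.__setattr__(self, "ca", ca)
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise StructureError(f"residue {self.key}: invalid aa letter {self.aa!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        keys = [(r.seq_number, r.insertion_code) for r in self.residues]
        if keys != sorted(keys):
            raise StructureError(f"chain {self.chain_id}: residues not sorted")
        if len(set(keys)) != len(keys):
            raise StructureError(f"chain {self.chain_id}: duplicate residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)


@dataclass(frozen=True)
class MembraneFrame:
    """Implicit membrane: ``normal`` points EC-ward, mid-plane at depth 0."""

    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    z_offset: float = 0.0
    core_half_width: float = 15.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if not math.isfinite(norm) or norm == 0.0:
            raise StructureError("membrane normal must be a nonzero vector")
        object.__setattr__(self, "normal", n / norm)


def z_of(residue: Residue, frame: MembraneFrame) -> float:
    """Signed membrane depth of a residue's Cα (positive = EC side)."""
    return float(np.dot(frame.normal, residue.ca) - frame.z_offset)


@dataclass
class StructureModel:
    id: str
    chains: list[Chain]
    frame: MembraneFrame | None = None

    def __post_init__(self) -> None:
        if not any(len(c) for c in self.chains):
            raise EmptyStructureError(f"structure {self.id}: no residues")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy (frame, if any, transformed jointly)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        chains = [
            Chain(c.chain_id, [replace(r, ca=rotation @ r.ca + translation) for r in c])
            for c in self.chains
        ]
        frame = None
        if self.frame is not None:
            normal = rotation @ self.frame.normal
            z_offset = self.frame.z_offset + float(np.dot(normal, translation))
            frame = MembraneFrame(normal, z_offset, self.frame.core_half_width)
        return StructureModel(self.id, chains, frame)


def _residue_one_letter(name: str) -> str | None:
    """Map a residue name to one letter, or None if not amino-acid-like."""
    if name in _THREE_TO_ONE:
        return _THREE_TO_ONE[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code in STANDARD_AA else "X"
    return None


def _pick_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    """The Cα of a residue: highest occupancy wins, then label order."""
    best = None
    for atom in res:
        if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
            continue
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a Cα-only :class:`StructureModel`.

    Only the first model of multi-model files is used; residues without a Cα
    are dropped; alternate locations are resolved by highest occupancy and
    then label order.  Amino acids with nonstandard names become ``X`` unless
    mappable to a parent standard residue.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        seen: set[tuple[int, str]] = set()
        for res in ch:
            aa = _residue_one_letter(res.name)
            if aa is None:
                continue
            ca = _pick_ca(res)
            if ca is None:
                continue
            seqid = res.seqid.num
            icode = res.seqid.icode.strip()
            if (seqid, icode) in seen:  # altloc split across residue entries
                continue
            seen.add((seqid, icode))
            residues.append(
                Residue(ch.name, seqid, icode, aa, np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
            )
        if residues:
            residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            chains.append(Chain(ch.name, residues))
    if not chains:
        raise EmptyStructureError(f"{path}: structure has zero Cα atoms")
    return StructureModel(path.stem.upper(), chains, frame=None)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a Cα-only PDB file with standard ATOM records."""
    lines: list[str] = []
    serial = 1
    for chain in model.chains:
        for r in chain:
            resname = {v: k for k, v in _THREE_TO_ONE.items() if k in (
                "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
                "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
                "TYR", "VAL")}.get(r.aa, "UNK")
            icode = r.insertion_code or " "
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {chain.chain_id[:1]}"
                f"{r.seq_number:4d}{icode:1s}   "
                f"{r.ca[0]:8.3f}{r.ca[1]:8.3f}{r.ca[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {' C':>2s}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def orient_fallback(
    structure: StructureModel,
    segments: Sequence,
    n_term_side: str = "EC",
) -> MembraneFrame:
    """Build a membrane frame from TM segment axes when OPM orientation is absent.

    The normal is the normalized mean of the segment axis vectors after sign
    flips into a common hemisphere; the offset centres the mid-plane on the
    mean segment midpoint.  ``n_term_side`` states which side of the membrane
    the start of the *first* segment sits on and fixes the EC direction.
    """
    if n_term_side not in ("EC", "IC"):
        raise ValueError("n_term_side must be 'EC' or 'IC'")
    if len(segments) < 2:
        raise InsufficientDataError("orient_fallback needs >= 2 TM segments")
    axes = np.array([np.asarray(s.axis, float) for s in segments])
    ref = axes[0]
    signs = np.where(axes @ ref >= 0.0, 1.0, -1.0)
    normal = (axes * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise InsufficientDataError("segment axes cancel; cannot define a normal")
    normal = normal / norm
    mids = np.array([np.asarray(s.centroid, float) for s in segments])
    z_offset = float((mids @ normal).mean())
    first = segments[0].first_residue
    z_first = float(np.dot(normal, np.asarray(first.ca, float)) - z_offset)
    wants_positive = n_term_side == "EC"
    if (z_first > 0) != wants_positive:
        normal = -normal
        z_offset = -z_offset
    return MembraneFrame(normal, z_offset)
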