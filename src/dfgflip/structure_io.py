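"""Reading, preparing and annotating kinase structures.

Structures are held as flat lists of :class:`AtomRecord` so that every
downstream geometric operation (cleft distances, lobe rotation, sidedness
vectors, pocket grids) can index atoms by ``(res_seq, i_code, name)`` without
caring about the source format. Parsing goes through :mod:`gemmi`; writing
uses PDB v3.3 fixed columns so that a parse/write/parse round trip is
idempotent at 3-decimal coordinate precision.

Preparation follows the standard recipe for docking-grade kinase models:
waters, ions and other heteroatoms are removed, and phosphorylated residues
(SEP/TPO/PTR) are demoted to their parent amino acids by renaming, dropping
the phosphate atoms. No atoms are rebuilt and no coordinates are moved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

__all__ = [
    "AtomRecord", "KinaseStructure", "KinaseAnnotation",
    "read_pdb", "write_pdb", "prepare_structure", "annotate",
    "read_annotation", "write_annotation", "STANDARD_AA",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: phospho-residue -> (parent residue, atoms belonging to the phosphate group)
PHOSPHO_DEMOTIONS: Mapping[str, str] = {"SEP": "SER", "TPO": "THR", "PTR": "TYR"}
_PHOSPHATE_ATOMS = {"P", "O1P", "O2P", "O3P", "OP1", "OP2", "OP3"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a protein model (PDB conventions)."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def moved_to(self, xyz: Iterable[float]) -> "AtomRecord":
        x, y, z = (float(v) for v in xyz)
        return replace(self, coord=(x, y, z))


@dataclass(frozen=True)
class KinaseAnnotation:
    """Functional residue numbering of a kinase catalytic domain.

    All geometry in the package is anchored to these residues: the DFG motif
    at the start of the activation loop, the catalytic Lys of the beta-sheet
    and the alphaC Glu that form the conserved salt bridge, the alphaC helix
    limits, the hinge range linking the two lobes, the last residue of the
    activation loop, and the last residue of the N-lobe (residues with
    ``res_seq <= nlobe_last`` belong to the N-lobe).
    """

    dfg_asp: int
    dfg_phe: int
    dfg_gly: int
    catalytic_lys: int
    alphaC_glu: int
    alphaC_start: int
    alphaC_end: int
    hinge_start: int
    hinge_end: int
    activation_loop_end: int
    nlobe_last: int

    def __post_init__(self) -> None:
        if self.dfg_phe != self.dfg_asp + 1:
            raise ValueError(
                f"dfg_phe ({self.dfg_phe}) must be dfg_asp+1 ({self.dfg_asp + 1})"
            )
        if self.dfg_gly != self.dfg_asp + 2:
            raise ValueError(
                f"dfg_gly ({self.dfg_gly}) must be dfg_asp+2 ({self.dfg_asp + 2})"
            )
        if not self.alphaC_start < self.alphaC_end:
            raise ValueError("alphaC_start must be < alphaC_end")
        if not self.hinge_start <= self.hinge_end:
            raise ValueError("hinge_start must be <= hinge_end")
        if not self.dfg_asp < self.activation_loop_end:
            raise ValueError("dfg_asp must precede activation_loop_end")

    @property
    def hinge_middle(self) -> int:
        """Integer midpoint of the hinge range (floor on ties)."""
        return (self.hinge_start + self.hinge_end) // 2


@dataclass
class KinaseStructure:
    """Single-chain protein model as an ordered atom list."""

    atoms: list[AtomRecord]
    chain_filter: str = "A"
    source_id: str = ""
    annotation: KinaseAnnotation | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KinaseStructure):
            return NotImplemented
        return (
            self.atoms == other.atoms
            and self.chain_filter == other.chain_filter
        )

    # ---- residue / atom lookup -------------------------------------------

    def residues(self) -> list[tuple[int, str]]:
        """Ordered unique (res_seq, i_code) keys."""
        seen: dict[tuple[int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.res_seq, a.i_code), None)
        return list(seen)

    def residue_atoms(self, res_seq: int, i_code: str = " ") -> list[AtomRecord]:
        return [a for a in self.atoms
                if a.res_seq == res_seq and a.i_code == i_code]

    def residue_name(self, res_seq: int, i_code: str = " ") -> str:
        atoms = self.residue_atoms(res_seq, i_code)
        if not atoms:
            raise KeyError(f"residue {res_seq} not found")
        return atoms[0].res_name

    def atom(self, res_seq: int, name: str, i_code: str = " ") -> AtomRecord:
        for a in self.atoms:
            if a.res_seq == res_seq and a.i_code == i_code and a.name == name:
                return a
        raise KeyError(f"atom {name} of residue {res_seq} not found")

    def atom_coord(self, res_seq: int, name: str, i_code: str = " ") -> np.ndarray:
        return np.asarray(self.atom(res_seq, name, i_code).coord, dtype=float)

    def ca_coords(self, res_seqs: Iterable[int] | None = None) -> np.ndarray:
        """CA coordinates, in residue order (optionally restricted)."""
        wanted = None if res_seqs is None else set(res_seqs)
        out = [a.coord for a in self.atoms
               if a.name == "CA" and (wanted is None or a.res_seq in wanted)]
        return np.asarray(out, dtype=float).reshape(-1, 3)

    def ca_map(self) -> dict[tuple[int, str], np.ndarray]:
        return {(a.res_seq, a.i_code): np.asarray(a.coord)
                for a in self.atoms if a.name == "CA"}

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        out = [a.coord for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.asarray(out, dtype=float).reshape(-1, 3)

    def with_atoms(self, atoms: list[AtomRecord]) -> "KinaseStructure":
        return KinaseStructure(atoms=atoms, chain_filter=self.chain_filter,
                               source_id=self.source_id, annotation=self.annotation)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "KinaseStructure":
        """Apply a rigid transform x -> R x + t to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        moved = [a.moved_to(R @ np.asarray(a.coord) + t) for a in self.atoms]
        return self.with_atoms(moved)


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken toward altloc 'A'."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        if atom.occ > prev.occ or (
            atom.occ == prev.occ and (atom.altloc or "A") < (prev.altloc or "A")
        ):
            best[atom.name] = atom
    # preserve file order of the retained atoms
    kept = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in kept]


def read_pdb(path: str | Path, chain: str, include_het: bool = False) -> KinaseStructure:
    """Read one chain of a PDB (or mmCIF) file.

    HETATM records are excluded by default; alternate locations are resolved
    to the highest-occupancy copy (ties -> altloc 'A').
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if not st:
        raise ValueError(f"{path} contains no models")
    model = st[0]
    records: list[AtomRecord] = []
    serial = 0
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            is_het = res.het_flag == "H"
            if is_het and not include_het:
                continue
            icode = res.seqid.icode if res.seqid.icode.strip() else " "
            for atom in _resolve_altlocs(res):
                serial += 1
                records.append(AtomRecord(
                    serial=serial,
                    name=atom.name,
                    element=atom.element.name,
                    res_name=res.name,
                    chain_id=ch.name,
                    res_seq=res.seqid.num,
                    i_code=icode,
                    coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                ))
    if not records:
        raise ValueError(f"chain {chain!r} absent or empty in {path}")
    return KinaseStructure(atoms=records, chain_filter=chain, source_id=path.stem)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: 1-2 char elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(s: KinaseStructure, path: str | Path) -> Path:
    """Write fixed-column PDB v3.3 ATOM records (plus a TER and END)."""
    path = Path(path)
    lines = []
    a = None
    for i, a in enumerate(s.atoms, start=1):
        x, y, z = a.coord
        lines.append(
            "ATOM  {serial:>5d} {name}{alt}{res:>3s} {ch}{seq:>4d}{icode}   "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                serial=i, name=_format_atom_name(a.name, a.element), alt=" ",
                res=a.res_name, ch=a.chain_id, seq=a.res_seq, icode=a.i_code,
                x=x, y=y, z=z, occ=a.occupancy, b=a.b_factor,
                el=a.element.upper(),
            )
        )
    if a is not None:
        lines.append(
            "TER   {serial:>5d}      {res:>3s} {ch}{seq:>4d}{icode}".format(
                serial=len(s.atoms) + 1, res=a.res_name, ch=a.chain_id,
                seq=a.res_seq, icode=a.i_code,
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Preparation and annotation
# ---------------------------------------------------------------------------


def prepare_structure(s: KinaseStructure) -> KinaseStructure:
    """Strip waters/ions/ligands and demote phospho-residues by renaming.

    SEP -> SER, TPO -> THR, PTR -> TYR; the phosphate atoms (P, OxP) are
    dropped. Coordinates of retained atoms are untouched: missing-atom
    rebuilding is a modeling step outside this package's scope.
    """
    if not s.atoms:
        raise ValueError("empty structure")
    kept: list[AtomRecord] = []
    for a in s.atoms:
        if a.res_name in PHOSPHO_DEMOTIONS:
            if a.name in _PHOSPHATE_ATOMS:
                continue
            kept.append(replace(a, res_name=PHOSPHO_DEMOTIONS[a.res_name]))
        elif a.res_name in STANDARD_AA:
            kept.append(a)
        # anything else (HOH, ions, ligands) is dropped
    if not kept:
        raise ValueError("structure empty after preparation")
    return s.with_atoms(kept)


def annotate(s: KinaseStructure, ann: KinaseAnnotation) -> KinaseStructure:
    """Validate and attach a functional-residue annotation.

    Every referenced residue must exist with a CA atom; the DFG Asp and Phe
    additionally need their CG atoms, which the sidedness classifier uses.
    """
    referenced = {
        ann.dfg_asp, ann.dfg_phe, ann.dfg_gly, ann.catalytic_lys,
        ann.alphaC_glu, ann.alphaC_start, ann.alphaC_end,
        ann.hinge_start, ann.hinge_end, ann.hinge_middle,
        ann.activation_loop_end,
    }
    present = {seq for seq, _ in s.residues()}
    missing = sorted(r for r in referenced if r not in present)
    if missing:
        raise ValueError(
            "residue%s %s not found" % ("s" if len(missing) > 1 else "",
                                        ", ".join(map(str, missing)))
        )
    no_ca = sorted(
        r for r in referenced
        if not any(a.name == "CA" for a in s.residue_atoms(r))
    )
    if no_ca:
        raise ValueError(f"residues missing CA atoms: {no_ca}")
    out = s.with_atoms(list(s.atoms))
    out.annotation = ann
    return out


# ---------------------------------------------------------------------------
# Annotation files: flat "key value" text, one field per line
# ---------------------------------------------------------------------------

_ANN_FIELDS = [
    "dfg_asp", "dfg_phe", "dfg_gly", "catalytic_lys", "alphaC_glu",
    "alphaC_start", "alphaC_end", "hinge_start", "hinge_end",
    "activation_loop_end", "nlobe_last",
]


def read_annotation(path: str | Path) -> KinaseAnnotation:
    values: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'key value', got {raw!r}")
        key, value = parts
        if key not in _ANN_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = int(value)
    missing = [k for k in _ANN_FIELDS if k not in values]
    if missing:
        raise ValueError(f"{path}: missing keys {missing}")
    return KinaseAnnotation(**values)


def write_annotation(ann: KinaseAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{k} {getattr(ann, k)}\n" for k in _ANN_FIELDS)
    )
    return path
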