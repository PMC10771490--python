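"""Hierarchical coordinate model and PDB/mmCIF input/output.

The in-memory model is deliberately small: a :class:`Structure` holds ordered
:class:`Chain` objects, each an ordered list of :class:`Residue` objects with
their :class:`Atom` records.  Author residue numbering is the single numbering
scheme used throughout the package — residue labels such as V13 or F297 in the
septin literature are author numbers, so nothing is ever re-indexed.

Parsing and serialisation are delegated to :mod:`gemmi`; this module owns the
policies that gemmi leaves open (altloc resolution, polymer flagging, the
one-letter translation of nonstandard residues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "polymer_sequence",
    "THREE_TO_ONE",
]

# 20 standard amino acids; everything else maps to 'X' unless explicitly
# converted (see polymer_sequence's mse_as_met flag).
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no polymer chains."""


@dataclass
class Atom:
    """A single atom site.

    ``position`` is a length-3 float array in Å.  ``altloc`` is the empty
    string for un-alternated atoms; on read only one altloc survives per atom
    name (highest occupancy, ties broken alphabetically).
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_polymer: bool = True

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def residue(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    identifier: str = ""
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.identifier!r}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_residues()]

    def all_atoms(self) -> list[tuple[str, Residue, Atom]]:
        """Flat (chain_id, residue, atom) triples in file order."""
        out = []
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    out.append((ch.chain_id, res, atom))
        return out


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, tie broken by altloc letter."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _neg_ord(a.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            by_name[a.name] = a
    return list(by_name.values())


def _neg_ord(altloc: str) -> int:
    # sort helper: alphabetically first altloc wins a tie → larger score
    return -ord(altloc) if altloc else 0


def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".cif", ".mmcif") for s in suffixes):
        return "mmcif"
    if any(s in (".pdb", ".ent") for s in suffixes):
        return "pdb"
    # content sniff: mmCIF files open with a data_ block
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            return "mmcif" if stripped.startswith(("data_", "#")) else "pdb"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All polymer chains are returned; heteroatom residues (nucleotides such as
    GDP, ions, waters) are retained with ``is_polymer=False``.  Where altlocs
    conflict the highest-occupancy one is kept (tie → first alphabetically).

    Raises ``EmptyStructureError`` if no polymer chain is present and
    ``IOError``/``ValueError`` on unreadable input.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "pdb":
            gst = gemmi.read_pdb(str(path))
        else:
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"could not parse {path} as {format}: {exc}") from exc

    gst.setup_entities()
    structure = Structure(identifier=gst.name or path.stem)
    if len(gst) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = gst[0]  # first model only; NMR ensembles out of scope
    merged: dict[str, Chain] = {}
    for gchain in model:
        chain = merged.setdefault(gchain.name, Chain(chain_id=gchain.name))
        for gres in gchain:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    b_factor=ga.b_iso,
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                )
                for ga in gres
            ]
            atoms = _resolve_altlocs(atoms)
            chain.residues.append(
                Residue(
                    number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    atoms=atoms,
                    is_polymer=_is_amino_acid(gres.name),
                )
            )
    structure.chains = list(merged.values())
    if not structure.polymer_chains():
        raise EmptyStructureError(f"{path}: no polymer chains")
    for chain in structure.chains:
        for res in chain.polymer_residues():
            if res.ca is None:
                warnings.warn(
                    f"chain {chain.chain_id} residue {res.name}{res.number}"
                    f"{res.insertion_code} has no CA atom; downstream "
                    "CA-based operations will skip it",
                    stacklevel=2,
                )
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.identifier or "septkit"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    gst.setup_entities()
    return gst


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a :class:`Structure` to PDB or mmCIF.

    Chain order, author numbering, insertion codes and coordinates round-trip
    to format precision (1e-3 Å for PDB's fixed 8.3 fields).  The PDB dialect
    supports at most 62 single-character chain IDs; larger assemblies must be
    written as mmCIF.
    """
    path = Path(path)
    if not structure.chains or not any(len(c) for c in structure.chains):
        raise ValueError("refusing to write an empty structure")
    if format == "auto":
        format = _detect_format_for_write(path)
    if format == "pdb" and len(structure.chains) > 62:
        raise ValueError(
            f"{len(structure.chains)} chains exceed the PDB dialect's 62 "
            "single-character chain IDs; write mmCIF instead (format='mmcif')"
        )
    gst = _to_gemmi(structure)
    if format == "pdb":
        gst.write_pdb(str(path))
    elif format == "mmcif":
        gst.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def _detect_format_for_write(path: Path) -> str:
    if path.suffix.lower() in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def polymer_sequence(
    structure: Structure, chain_id: str, mse_as_met: bool = False
) -> list[tuple[int, int, str]]:
    """One-letter sequence of a chain's polymer residues.

    Returns an ordered list of ``(sequence_index, residue_number, code)``
    with 1-based sequence indices; author numbering (including gaps) is
    preserved in the second element.  Nonstandard residues become ``'X'``.
    Selenomethionine is NOT silently read as methionine — pass
    ``mse_as_met=True`` to opt in.
    """
    chain = structure.chain(chain_id)
    residues = chain.polymer_residues()
    if not residues:
        raise KeyError(f"chain {chain_id!r} has no polymer residues")
    out = []
    for i, res in enumerate(residues, start=1):
        code = THREE_TO_ONE.get(res.name)
        if code is None:
            code = "M" if (mse_as_met and res.name == "MSE") else "X"
        out.append((i, res.number, code))
    return out


def sequence_string(structure: Structure, chain_id: str, mse_as_met: bool = False) -> str:
    """Convenience: the chain's one-letter sequence as a plain string."""
    return "".join(code for _, _, code in polymer_sequence(structure, chain_id, mse_as_met))
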