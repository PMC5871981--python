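"""Minimal heavy-atom structure I/O for protein-ligand complexes.

Reads protein receptors from fixed-column PDB text and ligands from V2000
SDF/MOL blocks into a deliberately small in-memory model: element symbols,
Cartesian coordinates in angstroms, and (for ligands) a bond list.  That is
all the descriptor schemes downstream consume, so protonation states,
formal charges and residue-level bookkeeping are intentionally out of
scope.  Hydrogens are stripped on read: every descriptor in this package is
heavy-atom based.

The readers are strict about the fixed-column layouts and report the
offending line number on malformed input, which matters in practice because
structure files from heterogeneous sources fail in heterogeneous ways.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
import networkx as nx

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "StructureFormatError",
    "EmptyStructureError",
    "read_protein_pdb",
    "read_ligand_sdf",
    "write_protein_pdb",
    "write_ligand_sdf",
    "count_rotatable_bonds",
    "structure_to_csv",
    "structure_from_csv",
]

#: residue names treated as water and always excluded
WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

#: two-letter element symbols recognised when falling back to atom names
TWO_LETTER_ELEMENTS = {"CL", "BR", "FE", "ZN", "MG", "MN", "CA", "NA", "SE", "CU", "NI", "CO"}

HYDROGEN = {"H", "D"}


class StructureFormatError(ValueError):
    """Raised when a structure file violates its declared format."""


class EmptyStructureError(ValueError):
    """Raised when no heavy atoms survive filtering."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: uppercase element symbol, coordinates in angstroms,
    and the ordinal of the record in the source file."""

    element: str
    coords: tuple[float, float, float]
    source_index: int

    def __post_init__(self) -> None:
        if not self.element or not self.element.isalpha():
            raise ValueError(f"element must be alphabetic, got {self.element!r}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates: {self.coords}")


@dataclass
class MolecularStructure:
    """An ordered heavy-atom list with a role and an optional bond graph.

    ``bonds`` holds ``(i, j, order)`` tuples with 0-based atom indices and
    order in ``{1, 2, 3, "aromatic"}``; proteins typically carry no bonds.
    """

    atoms: list[AtomRecord]
    role: str  # "protein" | "ligand"
    bonds: list[tuple[int, int, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be 'protein' or 'ligand', got {self.role!r}")
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if order not in (1, 2, 3, "aromatic"):
                raise ValueError(f"unsupported bond order {order!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def coords_array(self):
        import numpy as np

        return np.array([a.coords for a in self.atoms], dtype=float)


def _element_from_name(atom_name: str) -> str:
    """Infer the element from a PDB atom-name field.

    Older PDB files omit columns 77-78; the convention then is that the
    element is the leading alphabetic part of the atom name, with CL/BR and
    common metals recognised as two-letter symbols.
    """
    token = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not token:
        return ""
    if token[:2] in TWO_LETTER_ELEMENTS:
        return token[:2]
    return token[0]


def read_protein_pdb(stream, include_cofactors: bool = False) -> MolecularStructure:
    """Parse fixed-column PDB text into a heavy-atom protein structure.

    ATOM records are always read; HETATM records are read only when
    ``include_cofactors`` is set, and waters are excluded in either case.
    Hydrogens and deuteriums are stripped.  Only the first model of a
    multi-model file is used, and alternate locations other than blank/'A'
    are skipped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    atoms: list[AtomRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        rec = raw[:6]
        if rec.startswith("ENDMDL"):
            break
        if rec not in ("ATOM  ", "HETATM"):
            continue
        line = raw.rstrip("\n")
        resname = line[17:20].strip().upper()
        if resname in WATER_RESNAMES:
            continue
        if rec == "HETATM" and not include_cofactors:
            continue
        altloc = line[16:17]
        if altloc not in (" ", "A", ""):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise StructureFormatError(
                f"line {lineno}: unparseable coordinates in {line[30:54]!r}"
            ) from exc
        element = line[76:78].strip().upper()
        if not element or not element.isalpha():
            element = _element_from_name(line[12:16])
        if not element:
            raise StructureFormatError(f"line {lineno}: cannot determine element")
        if element in HYDROGEN:
            continue
        atoms.append(AtomRecord(element, (x, y, z), lineno))
    if not atoms:
        raise EmptyStructureError("no heavy atoms remain after filtering")
    return MolecularStructure(atoms=atoms, role="protein")


def read_ligand_sdf(stream) -> MolecularStructure:
    """Parse the first V2000 MOL block of an SDF into a heavy-atom ligand.

    Hydrogens are removed and bond indices re-mapped onto the surviving
    heavy atoms; bonds that touched a hydrogen are dropped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if len(lines) < 4:
        raise StructureFormatError("SDF block shorter than the 4 header lines")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise StructureFormatError(f"line 4: bad counts line {counts!r}") from exc
    atom_end = 4 + n_atoms
    bond_end = atom_end + n_bonds
    if len(lines) < bond_end:
        raise StructureFormatError(
            f"counts line declares {n_atoms} atoms / {n_bonds} bonds "
            f"but only {len(lines) - 4} block lines are present"
        )
    raw_atoms: list[tuple[str, tuple[float, float, float]]] = []
    for k, line in enumerate(lines[4:atom_end], start=5):
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
        except ValueError as exc:
            raise StructureFormatError(f"line {k}: unparseable coordinates") from exc
        element = line[31:34].strip().upper()
        if not element or not element.isalpha():
            raise StructureFormatError(f"line {k}: bad element field {line[31:34]!r}")
        raw_atoms.append((element, (x, y, z)))
    raw_bonds: list[tuple[int, int, object]] = []
    for k, line in enumerate(lines[atom_end:bond_end], start=atom_end + 1):
        try:
            a = int(line[0:3]) - 1
            b = int(line[3:6]) - 1
            code = int(line[6:9])
        except ValueError as exc:
            raise StructureFormatError(f"line {k}: bad bond record") from exc
        if not (0 <= a < n_atoms and 0 <= b < n_atoms) or a == b:
            raise StructureFormatError(f"line {k}: bond indices out of range")
        order: object = "aromatic" if code == 4 else code
        raw_bonds.append((a, b, order))

    keep = [i for i, (el, _) in enumerate(raw_atoms) if el not in HYDROGEN]
    if not keep:
        raise EmptyStructureError("no heavy atoms remain after hydrogen removal")
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [AtomRecord(raw_atoms[old][0], raw_atoms[old][1], old + 1) for old in keep]
    bonds = [
        (remap[a], remap[b], order)
        for a, b, order in raw_bonds
        if a in remap and b in remap
    ]
    return MolecularStructure(atoms=atoms, role="ligand", bonds=bonds)


def write_protein_pdb(mol: MolecularStructure, stream) -> None:
    """Write a structure as minimal PDB ATOM records (coordinates %8.3f)."""
    for i, atom in enumerate(mol.atoms, start=1):
        name = atom.element[:4].rjust(2).ljust(4)
        stream.write(
            f"ATOM  {i:5d} {name} UNK A{(i - 1) % 9999 + 1:4d}    "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"  1.00  0.00          {atom.element:>2s}\n"
        )
    stream.write("END\n")


def write_ligand_sdf(mol: MolecularStructure, stream, title: str = "ligand") -> None:
    """Write a structure as a V2000 MOL block followed by ``$$$$``."""
    stream.write(f"{title}\n  sfbench\n\n")
    stream.write(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000\n")
    for atom in mol.atoms:
        x, y, z = atom.coords
        stream.write(f"{x:10.4f}{y:10.4f}{z:10.4f} {atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n")
    for a, b, order in mol.bonds:
        code = 4 if order == "aromatic" else int(order)
        stream.write(f"{a + 1:3d}{b + 1:3d}{code:3d}  0  0  0  0\n")
    stream.write("M  END\n$$$$\n")


def count_rotatable_bonds(mol: MolecularStructure) -> int:
    """Count rotatable bonds: acyclic single bonds between non-terminal atoms.

    A bond is rotatable when its order is 1, it is not part of any ring
    (i.e. it is a bridge of the bond graph), and both endpoints have at
    least two heavy-atom neighbours.  This is the torsion-count convention
    used by empirical docking scores, without amide-bond perception.
    """
    if mol.bonds is None:
        raise ValueError("structure has no bond list")
    if not mol.bonds:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    for a, b, _ in mol.bonds:
        g.add_edge(a, b)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    count = 0
    for a, b, order in mol.bonds:
        if order != 1:
            continue
        if frozenset((a, b)) not in bridges:
            continue  # ring bond
        if g.degree(a) >= 2 and g.degree(b) >= 2:
            count += 1
    return count


def structure_to_csv(mol: MolecularStructure, stream) -> None:
    """Dump atoms in the canonical internal CSV dialect (id,element,x,y,z)."""
    writer = csv.writer(stream)
    writer.writerow(["id", "element", "x", "y", "z"])
    for i, atom in enumerate(mol.atoms):
        writer.writerow([i, atom.element, repr(atom.coords[0]), repr(atom.coords[1]), repr(atom.coords[2])])


def structure_from_csv(stream, role: str = "protein") -> MolecularStructure:
    """Re-read the canonical CSV dump; exact inverse of ``structure_to_csv``."""
    reader = csv.reader(stream)
    header = next(reader)
    if header[:5] != ["id", "element", "x", "y", "z"]:
        raise StructureFormatError(f"unexpected header {header!r}")
    atoms = [
        AtomRecord(row[1], (float(row[2]), float(row[3]), float(row[4])), int(row[0]))
        for row in reader
        if row
    ]
    if not atoms:
        raise EmptyStructureError("empty canonical dump")
    return MolecularStructure(atoms=atoms, role=role)
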