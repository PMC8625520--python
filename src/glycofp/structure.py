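"""Domain model for multi-frame molecular systems and PDB input/output.

A :class:`MolecularSystem` partitions residues into roles (receptor,
ligand, water, ion, other) and carries one or more coordinate
:class:`Frame` objects.  Multi-model PDB files are the trajectory
format: each ``MODEL``/``ENDMDL`` block is one frame.  Parsing and
serialisation are delegated to biotite; this module only adds the role
bookkeeping and the flat atom indexing the interaction detectors need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Atom",
    "Residue",
    "Frame",
    "MolecularSystem",
    "DEFAULT_ROLE_RULES",
    "StructureError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
]

#: Standard amino-acid three-letter codes (receptor role by default).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}

#: Monatomic ion residue names recognised by the default role rules.
ION_RESIDUES = {"NA", "MG", "CA", "CL", "K"}

#: Hyaluronate building blocks: D-glucuronate and N-acetyl-D-glucosamine.
LIGAND_RESIDUES = {"GCU", "NAG"}

DEFAULT_ROLE_RULES = {
    **{name: "receptor" for name in AMINO_ACIDS},
    **{name: "ligand" for name in LIGAND_RESIDUES},
    "HOH": "water",
    "WAT": "water",
    **{name: "ion" for name in ION_RESIDUES},
}

ROLES = ("receptor", "ligand", "water", "ion", "other")


class StructureError(ValueError):
    """Malformed or inconsistent coordinate input."""


class SelectionError(ValueError):
    """Ill-formed atom selection predicate."""


@dataclass
class Atom:
    """One atom: identity plus its base-frame position.

    ``index`` is the row of this atom in every frame's coordinate
    array; per-frame positions are ``frame.coords[atom.index]``.
    """

    serial: int
    name: str
    element: str
    coord: np.ndarray
    index: int = -1
    formal_charge: int = 0
    residue: "Residue | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise StructureError(f"atom {self.name} has empty element")


@dataclass
class Residue:
    name: str
    chain_id: str
    number: int
    atoms: list[Atom] = field(default_factory=list)
    role: str = "other"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in {self.name} {self.chain_id}{self.number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chain_id, self.name, self.number)


@dataclass
class Frame:
    """Coordinates for every atom of the system at one trajectory point."""

    index: int
    coords: np.ndarray
    time: float | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("frame coordinates must have shape (n_atoms, 3)")


class MolecularSystem:
    """Residues with roles plus an ordered list of coordinate frames."""

    def __init__(self, residues: list[Residue], frames: list[Frame] | None = None):
        self.residues = residues
        self.atoms: list[Atom] = []
        for res in residues:
            if res.role not in ROLES:
                raise StructureError(f"unknown role {res.role!r} for residue {res.name}")
            names = [a.name for a in res.atoms]
            if len(names) != len(set(names)):
                raise StructureError(
                    f"duplicate atom names in residue {res.name} {res.chain_id}{res.number}"
                )
            for a in res.atoms:
                a.residue = res
                a.index = len(self.atoms)
                self.atoms.append(a)
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise StructureError("atom serial numbers are not unique")
        if frames is None:
            coords = np.array([a.coord for a in self.atoms], dtype=float)
            frames = [Frame(0, coords.reshape(-1, 3))]
        for fr in frames:
            if fr.coords.shape[0] != len(self.atoms):
                raise StructureError(
                    f"frame {fr.index} has {fr.coords.shape[0]} atoms, "
                    f"system has {len(self.atoms)}"
                )
        self.frames = frames
        for res in residues:
            if res.role == "ion" and len(res.atoms) != 1:
                raise StructureError(
                    f"ion residue {res.name} {res.number} has {len(res.atoms)} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def residues_with_role(self, role: str) -> list[Residue]:
        if role not in ROLES:
            raise SelectionError(f"unknown role {role!r}; valid roles: {ROLES}")
        return [r for r in self.residues if r.role == role]

    def atoms_with_role(self, role: str) -> list[Atom]:
        return [a for r in self.residues_with_role(role) for a in r.atoms]


def _assign_role(res_name: str, n_atoms: int, hetero: bool,
                 role_rules: dict[str, str]) -> str:
    """Role for one residue.

    A HETATM residue named like an ion (e.g. calcium "CA") is only
    treated as an ion when it is a single-atom residue; protein "CA"
    alpha-carbon atom names never reach this function since roles are
    per residue.
    """
    name = res_name.strip().upper()
    if name in ION_RESIDUES:
        return "ion" if (n_atoms == 1) else role_rules.get(name, "other")
    return role_rules.get(name, "other")


def read_pdb(path, role_rules: dict[str, str] | None = None) -> MolecularSystem:
    """Parse a (possibly multi-model) PDB file into a MolecularSystem.

    MODEL/ENDMDL blocks become frames; a file without MODEL records
    yields a single frame.  Roles are assigned per residue from
    ``role_rules`` (residue name -> role), falling back to
    :data:`DEFAULT_ROLE_RULES`.
    """
    rules = dict(DEFAULT_ROLE_RULES)
    if role_rules:
        rules.update({k.strip().upper(): v for k, v in role_rules.items()})

    try:
        pdb_file = pdb.PDBFile.read(path)
        stack = pdb_file.get_structure(model=None, extra_fields=["charge", "atom_id"])
    except Exception as exc:  # biotite raises InvalidFileError / ValueError
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    n = stack.array_length()
    if n == 0:
        return MolecularSystem([], [Frame(0, np.zeros((0, 3)))])

    first = stack[0]
    residues: list[Residue] = []
    starts = struc.get_residue_starts(first, add_exclusive_stop=True)
    for i in range(len(starts) - 1):
        lo, hi = starts[i], starts[i + 1]
        res = Residue(
            name=str(first.res_name[lo]).strip(),
            chain_id=str(first.chain_id[lo]).strip(),
            number=int(first.res_id[lo]),
        )
        for j in range(lo, hi):
            serial = int(first.atom_id[j]) if first.atom_id[j] > 0 else j + 1
            element = str(first.element[j]).strip() or _guess_element(first.atom_name[j])
            res.atoms.append(Atom(
                serial=serial,
                name=str(first.atom_name[j]).strip(),
                element=element.capitalize(),
                coord=np.array(first.coord[j], dtype=float),
                formal_charge=int(first.charge[j]),
            ))
        res.role = _assign_role(res.name, len(res.atoms), bool(first.hetero[lo]), rules)
        residues.append(res)

    frames = [Frame(m, np.array(stack.coord[m], dtype=float))
              for m in range(stack.stack_depth())]
    return MolecularSystem(residues, frames)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise StructureError("atom record with empty name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0]


def write_pdb(system: MolecularSystem, path) -> None:
    """Serialise a system to a (multi-model, fixed-column) PDB file.

    Round-trip guarantee: reading the written file reproduces atom
    names, residue numbering, roles under the same rules, and
    coordinates to the PDB precision of 3 decimals.
    """
    n = system.n_atoms
    array = struc.AtomArray(n)
    for a in system.atoms:
        if len(a.name) > 4:
            raise StructureError(f"atom name {a.name!r} exceeds 4 characters")
    array.coord = np.array([a.coord for a in system.atoms]).reshape(n, 3)
    array.chain_id = np.array([a.residue.chain_id for a in system.atoms], dtype="U4")
    array.res_id = np.array([a.residue.number for a in system.atoms], dtype=int)
    array.res_name = np.array([a.residue.name for a in system.atoms], dtype="U5")
    array.atom_name = np.array([a.name for a in system.atoms], dtype="U6")
    array.element = np.array([a.element.upper() for a in system.atoms], dtype="U2")
    array.hetero = np.array(
        [a.residue.role in ("ligand", "water", "ion", "other")
         for a in system.atoms], dtype=bool)
    array.set_annotation("charge", np.array(
        [a.formal_charge for a in system.atoms], dtype=int))
    if system.n_frames == 1:
        array.coord = system.frames[0].coords
        obj = array
    else:
        obj = struc.stack([array] * system.n_frames)
        obj.coord = np.stack([fr.coords for fr in system.frames])
    out = pdb.PDBFile()
    out.set_structure(obj)
    out.write(str(path))


def select_atoms(system: MolecularSystem, *, role: str | None = None,
                 chain: str | None = None, resname: str | None = None,
                 resnum: int | None = None, name: str | None = None,
                 element: str | None = None) -> list[Atom]:
    """Atoms matching every given predicate, in stable serial order."""
    if role is not None and role not in ROLES:
        raise SelectionError(f"unknown role {role!r}; valid roles: {ROLES}")
    out = []
    for a in system.atoms:
        r = a.residue
        if role is not None and r.role != role:
            continue
        if chain is not None and r.chain_id != chain:
            continue
        if resname is not None and r.name != resname:
            continue
        if resnum is not None and r.number != resnum:
            continue
        if name is not None and a.name != name:
            continue
        if element is not None and a.element.upper() != element.upper():
            continue
        out.append(a)
    return sorted(out, key=lambda a: a.serial)
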