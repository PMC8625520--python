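"""Chemical perception tables for interaction detection.

Covers: hydrogen-bond donor/acceptor flagging, formal-charge centres of
titratable groups at physiological pH, hydrophobic carbon classes, the
per-element hydrogen-bond radii used by the ionic-contact distance
adjustment, and the oxygen-class labels of the hyaluronate disaccharide
(GCU = D-glucuronate, NAG = N-acetyl-D-glucosamine).

Covalent attachment is perceived geometrically within each residue
(H within 1.2 Å of a heavy atom is bonded to it; heavy atoms within
1.85 Å are bonded), which is exact on the idealised templates shipped
with this package and robust on ordinary PDB geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AMINO_ACIDS, Atom, MolecularSystem, Residue

__all__ = [
    "TypingTables",
    "ChargeCenter",
    "TypingError",
    "MissingHydrogensError",
    "assign_protonation",
    "find_donors_acceptors",
    "classify_hydrophobic_carbons",
    "charge_center",
    "charge_centers",
    "assign_oxygen_classes",
    "covalent_neighbors",
    "DEFAULT_OXYGEN_CLASS_MAP",
]

# Geometric bond-perception cutoffs (Å).
H_BOND_CUTOFF = 1.2      # H attached to heavy atom
HEAVY_BOND_CUTOFF = 1.85  # heavy-heavy covalent bond


class TypingError(ValueError):
    """Residue or atom outside the known chemistry tables."""


class MissingHydrogensError(TypingError):
    """An H-dependent detector was asked to run on a hydrogen-free system."""


@dataclass
class TypingTables:
    """Tunable chemistry tables, all overridable from config.

    ``hbond_radii`` are the per-element radii subtracted from the raw
    centre-centre distance of an ionic contact; values for N/O and the
    ions are package defaults (the convention, not a measured set).
    """

    hbond_radii: dict[str, float] = field(default_factory=lambda: {
        "N": 1.75, "O": 1.70, "C": 1.80, "S": 1.80,
        "NA": 1.00, "MG": 0.85, "CA": 1.10, "CL": 1.75, "K": 1.33,
    })
    his_protonated: bool = False   # HIS neutral at pH 7.4 by default
    hydrophobic_cutoff: float = 4.5  # Å, between qualifying carbons
    water_bridge_threshold: float = 3.0  # Å, H...acceptor leg
    ionic_range: tuple[float, float] = (0.0, 1.5)  # Å, adjusted distance
    hbond_energy_threshold: float = 6.25  # kJ/mol, strict ">"

    def radius(self, key: str) -> float:
        try:
            return self.hbond_radii[key.upper()]
        except KeyError as exc:
            raise TypingError(f"no hydrogen-bond radius for element {key!r}") from exc


# --- protonation -----------------------------------------------------------

# Side-chain charges of the standard residues at pH 7.4; HIS is a switch.
_SIDECHAIN_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}
_ION_CHARGE = {"NA": +1, "K": +1, "MG": +2, "CA": +2, "CL": -1}
# Atom carrying the formal charge in the PDB bookkeeping sense.
_CHARGE_ATOM = {"ASP": "OD2", "GLU": "OE2", "LYS": "NZ", "ARG": "CZ",
                "GCU": "O6B"}


def assign_protonation(residue: Residue, pH: float = 7.4,
                       tables: TypingTables | None = None) -> dict[str, int]:
    """Per-atom formal charges of one residue at the given pH.

    At pH 7.4: ASP/GLU carboxylates are deprotonated (−1), LYS and ARG
    protonated (+1), HIS neutral unless ``tables.his_protonated``; the
    glucuronate carboxylate of GCU (pKa ≈ 3) is deprotonated (−1);
    water is neutral and ions carry their nominal charge.  Side effects:
    the returned charges are also written onto the residue's atoms.
    """
    tables = tables or TypingTables()
    name = residue.name.upper()
    charges = {a.name: 0 for a in residue.atoms}
    if name in ("HOH", "WAT"):
        pass
    elif name in _ION_CHARGE and len(residue.atoms) == 1:
        charges[residue.atoms[0].name] = _ION_CHARGE[name]
    elif name == "HIS":
        if tables.his_protonated:
            # charge bookkeeping on ND1; the centre is the ring midpoint
            key = "ND1" if residue.has_atom("ND1") else residue.atoms[0].name
            charges[key] = +1
    elif name in _SIDECHAIN_CHARGE:
        atom = _CHARGE_ATOM[name]
        if residue.has_atom(atom):
            charges[atom] = _SIDECHAIN_CHARGE[name]
    elif name == "GCU":
        for cand in ("O6B", "O6A", "O6"):
            if residue.has_atom(cand):
                charges[cand] = -1
                break
    elif name in AMINO_ACIDS or name == "NAG":
        pass  # neutral at pH 7.4
    else:
        raise TypingError(f"unknown residue type {residue.name!r}")
    for a in residue.atoms:
        a.formal_charge = charges[a.name]
    return charges


# --- donors / acceptors ----------------------------------------------------

def covalent_neighbors(atom: Atom, frame_coords: np.ndarray | None = None
                       ) -> list[Atom]:
    """Atoms of the same residue covalently attached to ``atom``.

    Perceived geometrically; with ``frame_coords`` given, that frame's
    coordinates are used instead of the base coordinates.
    """
    res = atom.residue
    def pos(a: Atom) -> np.ndarray:
        return frame_coords[a.index] if frame_coords is not None else a.coord
    out = []
    p0 = pos(atom)
    for other in res.atoms:
        if other is atom:
            continue
        d = float(np.linalg.norm(pos(other) - p0))
        if atom.element == "H" or other.element == "H":
            if atom.element == "H" and other.element == "H":
                continue
            if d <= H_BOND_CUTOFF:
                out.append(other)
        elif d <= HEAVY_BOND_CUTOFF:
            out.append(other)
    return out


def find_donors_acceptors(system: MolecularSystem, roles=("receptor", "ligand")
                          ) -> tuple[list[tuple[Atom, Atom]], list[Atom]]:
    """Hydrogen-bond donors and acceptors among the given roles.

    Returns ``(donor_pairs, acceptors)`` where ``donor_pairs`` is a list
    of (heavy donor atom, attached hydrogen) and ``acceptors`` are all
    N/O atoms.  Donor detection needs explicit hydrogens: if the
    selected atoms contain N/O but not a single hydrogen anywhere,
    a :class:`MissingHydrogensError` is raised.
    """
    atoms = [a for role in roles for a in system.atoms_with_role(role)]
    acceptors = [a for a in atoms if a.element in ("N", "O")]
    any_h = any(a.element == "H" for a in atoms)
    if acceptors and not any_h:
        raise MissingHydrogensError(
            "donor detection requires explicit hydrogens; none present in roles "
            f"{roles}")
    donor_pairs = []
    for a in acceptors:
        for nb in covalent_neighbors(a):
            if nb.element == "H":
                donor_pairs.append((a, nb))
    return donor_pairs, acceptors


# --- hydrophobic carbon classes -------------------------------------------

#: Aromatic ring carbons per residue template (perception is not done).
AROMATIC_RING_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}


def classify_hydrophobic_carbons(residue: Residue) -> dict[str, str]:
    """Hydrophobic class of every carbon in a residue.

    Three qualifying classes: ``CH3`` (carbon carrying three
    hydrogens), ``CH2/CH`` (two hydrogens, or one hydrogen with three
    carbons attached), ``aromatic-CH`` (template ring carbon carrying
    at least one hydrogen); everything else is ``none``.  Alpha carbons
    of amino acids are excluded (class ``none``) except for glycine,
    whose CA carries two hydrogens and does qualify.
    """
    name = residue.name.upper()
    is_amino = name in AMINO_ACIDS
    ring = AROMATIC_RING_CARBONS.get(name, set())
    out: dict[str, str] = {}
    for atom in residue.atoms:
        if atom.element != "C":
            continue
        if is_amino and atom.name == "CA" and name != "GLY":
            out[atom.name] = "none"
            continue
        nbs = covalent_neighbors(atom)
        n_h = sum(1 for nb in nbs if nb.element == "H")
        n_c = sum(1 for nb in nbs if nb.element == "C")
        if atom.name in ring and n_h >= 1:
            out[atom.name] = "aromatic-CH"
        elif n_h == 3:
            out[atom.name] = "CH3"
        elif n_h == 2 or (n_h == 1 and n_c == 3):
            out[atom.name] = "CH2/CH"
        else:
            out[atom.name] = "none"
    return out


# --- formal charge centres -------------------------------------------------

@dataclass
class ChargeCenter:
    """Location of one formal integer charge, possibly a pseudo-point.

    For delocalised carboxylates the centre is the midpoint of the two
    oxygens; ``radius_element`` is the element whose hydrogen-bond
    radius applies (the element of the nearest real atom for
    pseudo-points).
    """

    residue: Residue
    position: np.ndarray
    charge: int
    radius_element: str
    atoms: tuple[Atom, ...]  # real atoms defining the centre
    label: str = ""

    def position_in(self, frame_coords: np.ndarray) -> np.ndarray:
        pts = np.array([frame_coords[a.index] for a in self.atoms])
        return pts.mean(axis=0)


def charge_center(residue: Residue, tables: TypingTables | None = None
                  ) -> ChargeCenter:
    """Charge centre of a charged residue.

    LYS: NZ (+1); ARG: CZ (+1); protonated HIS: ND1/NE2 midpoint (+1);
    ASP/GLU and the GCU carboxylate: midpoint of the two carboxylate
    oxygens (−1); monatomic ions: their single atom with nominal
    charge.  Raises :class:`TypingError` for neutral residues.
    """
    tables = tables or TypingTables()
    name = residue.name.upper()

    def midpoint(n1: str, n2: str, q: int, elem: str) -> ChargeCenter:
        if not (residue.has_atom(n1) and residue.has_atom(n2)):
            raise TypingError(
                f"{name} fragment lacks the centre atoms {n1}/{n2}")
        a1, a2 = residue.atom(n1), residue.atom(n2)
        pos = (a1.coord + a2.coord) / 2.0
        return ChargeCenter(residue, pos, q, elem, (a1, a2),
                            label=f"{name}:{n1}/{n2}")

    if name in _ION_CHARGE and len(residue.atoms) == 1:
        a = residue.atoms[0]
        return ChargeCenter(residue, a.coord.copy(), _ION_CHARGE[name],
                            name, (a,), label=f"{name}:{a.name}")
    if name == "LYS":
        if not residue.has_atom("NZ"):
            raise TypingError("LYS fragment lacks the NZ centre atom")
        a = residue.atom("NZ")
        return ChargeCenter(residue, a.coord.copy(), +1, "N", (a,), "LYS:NZ")
    if name == "ARG":
        if not residue.has_atom("CZ"):
            raise TypingError("ARG fragment lacks the CZ centre atom")
        a = residue.atom("CZ")
        return ChargeCenter(residue, a.coord.copy(), +1, "C", (a,), "ARG:CZ")
    if name == "HIS":
        if not tables.his_protonated:
            raise TypingError("HIS is neutral under the current tables")
        return midpoint("ND1", "NE2", +1, "N")
    if name == "ASP":
        return midpoint("OD1", "OD2", -1, "O")
    if name == "GLU":
        return midpoint("OE1", "OE2", -1, "O")
    if name == "GCU":
        return midpoint("O6A", "O6B", -1, "O")
    raise TypingError(f"residue {residue.name!r} carries no formal charge centre")


def charge_centers(system: MolecularSystem, roles=("receptor", "ligand", "ion"),
                   tables: TypingTables | None = None) -> list[ChargeCenter]:
    """All charge centres of the system in the given roles."""
    tables = tables or TypingTables()
    out = []
    for role in roles:
        for res in system.residues_with_role(role):
            try:
                out.append(charge_center(res, tables))
            except TypingError:
                continue
    return out


# --- hyaluronate oxygen classes -------------------------------------------

#: Shipped convention mapping (residue, atom) -> class label.  The class
#: vocabulary is {O1..O10, N}; hydroxyl oxygens fall on O1, O2, O8, O10,
#: the carboxylate on O5, ring oxygens on O4, the glycosidic bridge on
#: O7, the anomeric hydroxyl of NAG on O6, the acetyl carbonyl on O9 and
#: the acetamido nitrogen on N.  This assignment is a documented package
#: convention (map version below is echoed in all fingerprint outputs).
DEFAULT_OXYGEN_CLASS_MAP: dict[tuple[str, str], str] = {
    ("GCU", "O1"): "O1",
    ("GCU", "O2"): "O2",
    ("GCU", "O3"): "O3",
    ("GCU", "O5"): "O4",
    ("GCU", "O6A"): "O5",
    ("GCU", "O6B"): "O5",
    ("NAG", "O1"): "O6",
    ("NAG", "O3"): "O7",
    ("NAG", "O4"): "O8",
    ("NAG", "O5"): "O4",
    ("NAG", "O7"): "O9",
    ("NAG", "O6"): "O10",
    ("NAG", "N2"): "N",
}

OXYGEN_CLASS_MAP_VERSION = "glycofp-default-1"

#: Full class vocabulary in canonical order.
OXYGEN_CLASSES = tuple(f"O{i}" for i in range(1, 11)) + ("N",)


def assign_oxygen_classes(ligand_residues: list[Residue],
                          map_config: dict[tuple[str, str], str] | None = None,
                          strict: bool = True) -> dict[int, str]:
    """Class label for every ligand N/O atom, keyed by atom index.

    ``map_config`` overrides the shipped convention.  In strict mode an
    unmapped ligand N/O atom raises; in lenient mode it is labelled
    ``"?"``.
    """
    mapping = dict(DEFAULT_OXYGEN_CLASS_MAP)
    if map_config:
        mapping.update(map_config)
    bad = set(mapping.values()) - set(OXYGEN_CLASSES)
    if bad:
        raise TypingError(f"oxygen-class labels outside the vocabulary: {bad}")
    out: dict[int, str] = {}
    for res in ligand_residues:
        for atom in res.atoms:
            if atom.element not in ("N", "O"):
                continue
            key = (res.name.upper(), atom.name)
            if key in mapping:
                out[atom.index] = mapping[key]
            elif strict:
                raise TypingError(
                    f"ligand atom {res.name} {atom.name} has no oxygen-class label")
            else:
                out[atom.index] = "?"
    return out
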