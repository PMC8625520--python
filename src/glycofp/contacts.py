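"""Geometric detectors for water bridges, ionic contacts, cation
bridges and hydrophobic contacts.

Criteria, all evaluated per frame:

* **Water bridge** — a water molecule donating both of its hydrogens,
  one within 3.0 Å of a receptor N/O acceptor and the other within
  3.0 Å of a ligand N/O acceptor (distance-only rule; no angular term).
* **Ionic contact** — two formal-charge centres of opposite sign whose
  raw separation, after subtracting the hydrogen-bond radius of each
  centre, lies in [0, 1.5] Å.  Receptor–ligand, ion–receptor and
  ion–ligand pairings are all reported, with labels.
* **Cation bridge** — a cation simultaneously in ionic contact with at
  least one receptor anionic centre and one ligand anionic centre;
  every centre pair is enumerated.  The default species filter is
  {Ca, Mg}; Na can be included on request.
* **Hydrophobic contact** — a receptor carbon and a ligand carbon, both
  of qualifying hydrophobic class (CH3, CH2/CH or aromatic-CH), within
  4.5 Å (configurable).  Alpha carbons are excluded except glycine's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chemtype import (ChargeCenter, MissingHydrogensError, TypingTables,
                       charge_centers, classify_hydrophobic_carbons)
from .structure import Atom, Frame, MolecularSystem, Residue

__all__ = [
    "WaterBridge",
    "IonicContact",
    "CationBridge",
    "HydrophobicContact",
    "detect_water_bridges",
    "detect_ionic_contacts",
    "detect_cation_bridges",
    "detect_hydrophobic_contacts",
]


@dataclass
class WaterBridge:
    """One water double-donating to a receptor and a ligand acceptor."""

    water: Residue
    receptor_acceptor: Atom
    ligand_acceptor: Atom
    dist_receptor: float  # H...acceptor, Å, for the reported assignment
    dist_ligand: float

    def key(self):
        return (self.water.key, self.receptor_acceptor.serial,
                self.ligand_acceptor.serial)


@dataclass
class IonicContact:
    """Opposite-sign charge centres within the adjusted-distance range."""

    positive: ChargeCenter
    negative: ChargeCenter
    raw_distance: float
    adjusted_distance: float
    pairing: str  # "receptor-ligand", "ion-receptor", "ion-ligand"


@dataclass
class CationBridge:
    """A cation in simultaneous ionic contact with both solutes."""

    cation: ChargeCenter
    receptor_center: ChargeCenter
    ligand_center: ChargeCenter
    adjusted_receptor: float
    adjusted_ligand: float


@dataclass
class HydrophobicContact:
    atom_a: Atom          # receptor carbon
    atom_b: Atom          # ligand carbon
    class_a: str
    class_b: str
    distance: float


def detect_water_bridges(frame: Frame, system: MolecularSystem,
                         tables: TypingTables | None = None) -> list[WaterBridge]:
    """Water bridges in one frame; see the module docstring.

    Both hydrogen assignments are tried for every (water, receptor
    acceptor, ligand acceptor) triple and duplicates are collapsed; the
    recorded leg distances belong to the assignment with the smaller
    distance sum.  Requires explicit water hydrogens.
    """
    tables = tables or TypingTables()
    cutoff = tables.water_bridge_threshold
    waters = system.residues_with_role("water")
    if not waters:
        return []
    rec_acc = [a for a in system.atoms_with_role("receptor")
               if a.element in ("N", "O")]
    lig_acc = [a for a in system.atoms_with_role("ligand")
               if a.element in ("N", "O")]
    if not rec_acc or not lig_acc:
        return []
    c = frame.coords
    rec_tree = cKDTree(np.array([c[a.index] for a in rec_acc]))
    lig_tree = cKDTree(np.array([c[a.index] for a in lig_acc]))

    bridges: list[WaterBridge] = []
    for water in waters:
        hydros = [a for a in water.atoms if a.element == "H"]
        if len(hydros) < 2:
            raise MissingHydrogensError(
                f"water {water.chain_id}{water.number} lacks explicit hydrogens")
        h1, h2 = hydros[0], hydros[1]
        seen: dict[tuple, tuple[float, float]] = {}
        for ha, hb in ((h1, h2), (h2, h1)):
            r_hits = rec_tree.query_ball_point(c[ha.index], r=cutoff)
            l_hits = lig_tree.query_ball_point(c[hb.index], r=cutoff)
            for ri in r_hits:
                d_r = float(np.linalg.norm(c[ha.index] - c[rec_acc[ri].index]))
                for li in l_hits:
                    d_l = float(np.linalg.norm(c[hb.index] - c[lig_acc[li].index]))
                    key = (rec_acc[ri].serial, lig_acc[li].serial)
                    if key not in seen or d_r + d_l < sum(seen[key]):
                        seen[key] = (d_r, d_l)
        for (rs, ls), (d_r, d_l) in sorted(seen.items()):
            r_atom = next(a for a in rec_acc if a.serial == rs)
            l_atom = next(a for a in lig_acc if a.serial == ls)
            bridges.append(WaterBridge(water, r_atom, l_atom, d_r, d_l))
    return bridges


def _center_positions(centers: list[ChargeCenter], coords: np.ndarray
                      ) -> np.ndarray:
    return np.array([cc.position_in(coords) for cc in centers]).reshape(-1, 3)


def detect_ionic_contacts(frame: Frame, system: MolecularSystem,
                          tables: TypingTables | None = None) -> list[IonicContact]:
    """Ionic contacts in one frame.

    A contact is emitted when the raw centre–centre distance minus the
    two hydrogen-bond radii falls inside the configured adjusted range
    (default [0, 1.5] Å, both bounds inclusive).  ARG and protonated
    HIS centres are scanned like any other — whether they ever form
    contacts is a property of the coordinates, not of the detector.
    """
    tables = tables or TypingTables()
    lo, hi = tables.ionic_range
    c = frame.coords
    groups = {
        "receptor": charge_centers(system, ("receptor",), tables),
        "ligand": charge_centers(system, ("ligand",), tables),
        "ion": charge_centers(system, ("ion",), tables),
    }
    pairings = [("receptor", "ligand", "receptor-ligand"),
                ("ion", "receptor", "ion-receptor"),
                ("ion", "ligand", "ion-ligand")]
    out: list[IonicContact] = []
    for g1, g2, label in pairings:
        for cc1 in groups[g1]:
            for cc2 in groups[g2]:
                if cc1.charge * cc2.charge >= 0:
                    continue
                p1 = cc1.position_in(c)
                p2 = cc2.position_in(c)
                raw = float(np.linalg.norm(p1 - p2))
                adj = raw - (tables.radius(cc1.radius_element)
                             + tables.radius(cc2.radius_element))
                if lo <= adj <= hi:
                    pos, neg = (cc1, cc2) if cc1.charge > 0 else (cc2, cc1)
                    out.append(IonicContact(pos, neg, raw, adj, label))
    return out


#: Cation species included in bridge detection by default.
DEFAULT_BRIDGE_SPECIES = ("CA", "MG")


def detect_cation_bridges(frame: Frame, system: MolecularSystem,
                          species=DEFAULT_BRIDGE_SPECIES,
                          tables: TypingTables | None = None) -> list[CationBridge]:
    """Cation bridges in one frame: one bridge per (cation, receptor
    anionic centre, ligand anionic centre) combination in simultaneous
    ionic contact."""
    tables = tables or TypingTables()
    species = {s.upper() for s in species}
    ionic = detect_ionic_contacts(frame, system, tables)
    per_cation: dict[tuple, dict[str, list]] = {}
    for contact in ionic:
        if contact.pairing == "receptor-ligand":
            continue
        cation = contact.positive
        if cation.residue.role != "ion" or cation.residue.name.upper() not in species:
            continue
        side = "receptor" if contact.pairing == "ion-receptor" else "ligand"
        entry = per_cation.setdefault(cation.residue.key, {"cc": cation,
                                                           "receptor": [],
                                                           "ligand": []})
        entry[side].append(contact)
    bridges: list[CationBridge] = []
    for entry in per_cation.values():
        for rc in entry["receptor"]:
            for lc in entry["ligand"]:
                bridges.append(CationBridge(
                    entry["cc"], rc.negative, lc.negative,
                    rc.adjusted_distance, lc.adjusted_distance))
    return bridges


def detect_hydrophobic_contacts(frame: Frame, system: MolecularSystem,
                                cutoff: float | None = None,
                                tables: TypingTables | None = None
                                ) -> list[HydrophobicContact]:
    """Receptor–ligand hydrophobic carbon contacts within the cutoff."""
    tables = tables or TypingTables()
    if cutoff is None:
        cutoff = tables.hydrophobic_cutoff
    c = frame.coords

    def qualifying(role: str) -> list[tuple[Atom, str]]:
        out = []
        for res in system.residues_with_role(role):
            classes = classify_hydrophobic_carbons(res)
            for atom in res.atoms:
                cls = classes.get(atom.name, "none")
                if cls != "none":
                    out.append((atom, cls))
        return out

    rec = qualifying("receptor")
    lig = qualifying("ligand")
    if not rec or not lig:
        return []
    lig_tree = cKDTree(np.array([c[a.index] for a, _ in lig]))
    contacts = []
    for atom_a, cls_a in rec:
        for li in lig_tree.query_ball_point(c[atom_a.index], r=cutoff):
            atom_b, cls_b = lig[li]
            d = float(np.linalg.norm(c[atom_a.index] - c[atom_b.index]))
            contacts.append(HydrophobicContact(atom_a, atom_b, cls_a, cls_b, d))
    contacts.sort(key=lambda hc: (hc.atom_a.serial, hc.atom_b.serial))
    return contacts
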