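"""Synthetic coordinate systems with planted, exactly known interactions.

Every detector in this package is validated against fixtures built
here: small receptor/ligand fragment pairs placed at mid-criterion
geometry (a planted event) or just outside the criterion (a decoy),
isolated from each other on a coarse grid so ground truth is provable
by construction.  Also provides an idealised hyaluronate disaccharide
(GCU–NAG) whose oxygen inventory is fully covered by the shipped
oxygen-class map, and Gaussian-jitter pseudo-trajectories.

Planted geometries (margins in parentheses):

* hydrogen bond — H···A 2.2 Å, collinear donor, E = 20 kJ/mol
  (threshold crossing at 2.475 Å); decoy at 2.7 Å.
* water bridge — both H···acceptor legs 2.8 Å (threshold 3.0); decoy
  legs 3.3 Å.
* ionic contact — adjusted distance 0.75 Å (range [0, 1.5]); decoy 1.7.
* cation bridge — both legs adjusted 0.75 Å; decoy 1.7 both sides.
* hydrophobic contact — methyl carbons 4.0 Å apart (cutoff 4.5);
  decoy 4.9 Å.

None of this emulates real dynamics: fragments are rigid, waters are
ideal (O–H 0.957 Å, H–O–H 104.5°), and jitter is isotropic Gaussian
noise, not physics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .chemtype import assign_protonation, TypingTables
from .structure import Atom, Frame, MolecularSystem, Residue

__all__ = [
    "PlantedComplex",
    "make_toy_disaccharide",
    "make_planted_complex",
    "make_trajectory",
    "make_water",
]

_HBOND_HA = 2.2        # planted H...A distance, Å
_HBOND_DECOY = 2.7
_WB_LEG = 2.8          # planted water-bridge leg, Å
_WB_DECOY = 3.3
_IONIC_ADJ = 0.75      # planted adjusted ionic distance, Å
_IONIC_DECOY = 1.7
_PHOBIC_D = 4.0        # planted methyl-methyl distance, Å
_PHOBIC_DECOY = 4.9

_OH = 0.96     # hydroxyl O-H, Å
_WAT_OH = 0.957
_WAT_ANGLE = 104.5  # degrees
_CH = 1.09
_NH = 1.01
_CC = 1.52
_CO = 1.43     # single bond
_CARBOXYL_CO = 1.25
_CN = 1.45


def _rot_z(v: np.ndarray, degrees: float) -> np.ndarray:
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


class _Builder:
    """Accumulates atoms into residues with unique serial numbers."""

    def __init__(self):
        self.residues: list[Residue] = []
        self._serial = 0

    def residue(self, name: str, chain: str, number: int, role: str) -> Residue:
        res = Residue(name, chain, number, role=role)
        self.residues.append(res)
        return res

    def atom(self, res: Residue, name: str, element: str, pos) -> Atom:
        self._serial += 1
        a = Atom(self._serial, name, element, np.asarray(pos, dtype=float))
        res.atoms.append(a)
        return a


def _methyl_hydrogens(center: np.ndarray, away: np.ndarray) -> list[np.ndarray]:
    """Three H positions around ``center``, tilted away from ``away``."""
    axis = center - away
    axis = axis / np.linalg.norm(axis)
    # orthonormal basis around the axis
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, axis)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, probe)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = []
    for k in range(3):
        phi = 2 * np.pi * k / 3
        d = 0.34 * axis + 0.94 * (np.cos(phi) * u + np.sin(phi) * v)
        out.append(center + _CH * d / np.linalg.norm(d))
    return out


def make_water(b: _Builder, chain: str, number: int, origin: np.ndarray,
               u1: np.ndarray, in_plane: np.ndarray | None = None) -> Residue:
    """Ideal water with one O-H along ``u1``; the second H is rotated
    by the ideal angle within the plane spanned by ``u1`` and
    ``in_plane`` (default: any perpendicular)."""
    u1 = np.asarray(u1, float)
    u1 = u1 / np.linalg.norm(u1)
    if in_plane is None:
        in_plane = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(in_plane, u1)) > 0.9:
            in_plane = np.array([0.0, 1.0, 0.0])
    w = in_plane - np.dot(in_plane, u1) * u1
    w /= np.linalg.norm(w)
    t = np.radians(_WAT_ANGLE)
    u2 = np.cos(t) * u1 + np.sin(t) * w
    res = b.residue("HOH", chain, number, "water")
    b.atom(res, "O", "O", origin)
    b.atom(res, "H1", "H", origin + _WAT_OH * u1)
    b.atom(res, "H2", "H", origin + _WAT_OH * u2)
    return res


# --- toy hyaluronate disaccharide -----------------------------------------

def make_toy_disaccharide(b: _Builder | None = None, chain: str = "B",
                          start_number: int = 1,
                          offset: np.ndarray | None = None
                          ) -> tuple[Residue, Residue]:
    """Idealised GCU–NAG disaccharide (planar hexagon rings).

    Geometry is schematic — ring atoms sit on a 1.52 Å-radius hexagon
    with equatorial substituents and alternating axial hydrogens — but
    covalent perception, donor/acceptor flags, formal charges (the GCU
    carboxylate carries −1) and oxygen-class coverage are all exact.
    """
    own = b is None
    if own:
        b = _Builder()
    off = np.zeros(3) if offset is None else np.asarray(offset, float)
    R = _CC  # hexagon radius == ring bond length

    def hexagon(center, names, start_angle=0.0):
        pos = {}
        for k, name in enumerate(names):
            t = np.radians(start_angle + 60.0 * k)
            pos[name] = center + R * np.array([np.cos(t), np.sin(t), 0.0])
        return pos

    z = np.array([0.0, 0.0, 1.0])

    # GCU ring centred at the origin: C1 at 0 deg, going counter-clockwise
    gcu_center = off + np.zeros(3)
    gp = hexagon(gcu_center, ["C1", "C2", "C3", "C4", "C5", "O5"])
    gcu = b.residue("GCU", chain, start_number, "ligand")

    def radial(center, p, length):
        u = p - center
        u = u / np.linalg.norm(u)
        return p + length * u, u

    # equatorial substituents + axial hydrogens
    o1, u1 = radial(gcu_center, gp["C1"], _CO)
    o2, u2 = radial(gcu_center, gp["C2"], _CO)
    o3, u3 = radial(gcu_center, gp["C3"], _CO)
    c6, u5 = radial(gcu_center, gp["C5"], _CC)
    for nm, el, p in [
        ("C1", "C", gp["C1"]), ("H1", "H", gp["C1"] + _CH * z),
        ("O1", "O", o1), ("HO1", "H", o1 + _OH * u1),
        ("C2", "C", gp["C2"]), ("H2", "H", gp["C2"] - _CH * z),
        ("O2", "O", o2), ("HO2", "H", o2 + _OH * u2),
        ("C3", "C", gp["C3"]), ("H3", "H", gp["C3"] + _CH * z),
        ("O3", "O", o3), ("HO3", "H", o3 + _OH * u3),
        ("C4", "C", gp["C4"]), ("H4", "H", gp["C4"] - _CH * z),
        ("C5", "C", gp["C5"]), ("H5", "H", gp["C5"] + _CH * z),
        ("O5", "O", gp["O5"]),
        ("C6", "C", c6),
        ("O6A", "O", c6 + _CARBOXYL_CO * _rot_z(u5, 60.0)),
        ("O6B", "O", c6 + _CARBOXYL_CO * _rot_z(u5, -60.0)),
    ]:
        b.atom(gcu, nm, el, p)

    # glycosidic bridge: GCU C4 - O3(NAG) - C3(NAG), extending along -x
    u_link = (gp["C4"] - gcu_center) / R  # unit vector, 180 deg -> (-1, 0, 0)
    o3n = gp["C4"] + _CO * u_link
    c3n = o3n + _CO * u_link
    nag_center = c3n + R * u_link
    # NAG ring oriented so that C3 faces the bridge oxygen
    u_back = (c3n - nag_center) / np.linalg.norm(c3n - nag_center)
    base_angle = np.degrees(np.arctan2(u_back[1], u_back[0]))
    np_ = hexagon(nag_center, ["C3", "C4", "C5", "O5", "C1", "C2"],
                  start_angle=base_angle)

    nag = b.residue("NAG", chain, start_number + 1, "ligand")
    o1n, v1 = radial(nag_center, np_["C1"], _CO)
    o4n, v4 = radial(nag_center, np_["C4"], _CO)
    c6n, v5 = radial(nag_center, np_["C5"], _CC)
    o6n = c6n + _CO * v5
    n2, v2 = radial(nag_center, np_["C2"], _CN)
    c7 = n2 + _CN * v2
    o7 = c7 + 1.23 * _rot_z(v2, 60.0)
    c8 = c7 + _CC * _rot_z(v2, -60.0)
    for nm, el, p in [
        ("C1", "C", np_["C1"]), ("H1", "H", np_["C1"] + _CH * z),
        ("O1", "O", o1n), ("HO1", "H", o1n + _OH * v1),
        ("C2", "C", np_["C2"]), ("H2", "H", np_["C2"] - _CH * z),
        ("N2", "N", n2), ("HN2", "H", n2 + _NH * _rot_z(v2, 90.0)),
        ("C7", "C", c7), ("O7", "O", o7),
        ("C8", "C", c8),
        ("C3", "C", np_["C3"]), ("H3", "H", np_["C3"] + _CH * z),
        ("O3", "O", o3n),
        ("C4", "C", np_["C4"]), ("H4", "H", np_["C4"] - _CH * z),
        ("O4", "O", o4n), ("HO4", "H", o4n + _OH * v4),
        ("C5", "C", np_["C5"]), ("H5", "H", np_["C5"] + _CH * z),
        ("O5", "O", np_["O5"]),
        ("C6", "C", c6n),
        ("H61", "H", c6n + _CH * z), ("H62", "H", c6n - _CH * z),
        ("O6", "O", o6n), ("HO6", "H", o6n + _OH * v5),
    ]:
        b.atom(nag, nm, el, p)
    for h in _methyl_hydrogens(c8, c7):
        b.atom(nag, f"H8{len([a for a in nag.atoms if a.name.startswith('H8')]) + 1}",
               "H", h)
    assign_protonation(gcu)
    assign_protonation(nag)
    return gcu, nag


# --- planted interaction motifs -------------------------------------------

@dataclass
class PlantedComplex:
    """A synthetic system plus its ground-truth contact inventory."""

    system: MolecularSystem
    inventory: dict[str, int]
    participants: dict[str, list] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _plant_hbond(b, rnum, lnum, decoy=False):
    """Receptor SER O-H donating to a ligand GCU hydroxyl oxygen."""
    d = _HBOND_DECOY if decoy else _HBOND_HA
    ser = b.residue("SER", "A", rnum, "receptor")
    cb = np.array([0.0, 0.0, 0.0])
    og = np.array([_CO, 0.0, 0.0])
    hg = og + np.array([_OH, 0.0, 0.0])
    b.atom(ser, "CB", "C", cb)
    b.atom(ser, "OG", "O", og)
    b.atom(ser, "HG", "H", hg)
    gcu = b.residue("GCU", "B", lnum, "ligand")
    o2 = hg + np.array([d, 0.0, 0.0])
    c2 = o2 + _CO * np.array([0.5, np.sqrt(3) / 2, 0.0])
    ho2 = o2 + _OH * np.array([0.5, -np.sqrt(3) / 2, 0.0])
    b.atom(gcu, "C2", "C", c2)
    b.atom(gcu, "O2", "O", o2)
    b.atom(gcu, "HO2", "H", ho2)
    return [ser, gcu]


def _plant_water_bridge(b, rnum, lnum, wnum, decoy=False):
    """ASN carbonyl O -- water -- NAG acetyl carbonyl O."""
    leg = _WB_DECOY if decoy else _WB_LEG
    asn = b.residue("ASN", "A", rnum, "receptor")
    od1 = np.array([0.0, 0.0, 0.0])
    cg = od1 - np.array([1.23, 0.0, 0.0])
    b.atom(asn, "CG", "C", cg)
    b.atom(asn, "OD1", "O", od1)
    u1 = np.array([-1.0, 0.0, 0.0])          # water H1 -> OD1 direction
    ow = od1 - (leg + _WAT_OH) * u1
    t = np.radians(_WAT_ANGLE)
    u2 = np.array([-np.cos(t), np.sin(t), 0.0])  # unit, 104.5 deg from u1
    make_water(b, "W", wnum, ow, u1, in_plane=np.array([0.0, 1.0, 0.0]))
    o7 = ow + (leg + _WAT_OH) * u2
    c7 = o7 + _CO * u2
    nag = b.residue("NAG", "B", lnum, "ligand")
    b.atom(nag, "C7", "C", c7)
    b.atom(nag, "O7", "O", o7)
    return [asn, nag]


def _plant_ionic(b, rnum, lnum, tables: TypingTables, decoy=False):
    """LYS NZ against a GCU carboxylate at planted adjusted distance."""
    adj = _IONIC_DECOY if decoy else _IONIC_ADJ
    raw = adj + tables.radius("N") + tables.radius("O")
    lys = b.residue("LYS", "A", rnum, "receptor")
    nz = np.array([0.0, 0.0, 0.0])
    b.atom(lys, "CE", "C", nz + np.array([1.47, 0.0, 0.0]))
    b.atom(lys, "NZ", "N", nz)
    b.atom(lys, "HZ1", "H", nz + _NH * np.array([0.33, 0.94, 0.0]))
    gcu = b.residue("GCU", "B", lnum, "ligand")
    m = nz - np.array([raw, 0.0, 0.0])
    half = 1.085
    c6 = m - np.array([np.sqrt(_CARBOXYL_CO ** 2 - half ** 2), 0.0, 0.0])
    b.atom(gcu, "C6", "C", c6)
    b.atom(gcu, "O6A", "O", m + np.array([0.0, half, 0.0]))
    b.atom(gcu, "O6B", "O", m - np.array([0.0, half, 0.0]))
    assign_protonation(lys)
    assign_protonation(gcu)
    return [lys, gcu]


def _plant_cation_bridge(b, rnum, lnum, inum, species: str,
                         tables: TypingTables, decoy=False):
    """GLU carboxylate -- cation -- GCU carboxylate, both legs planted."""
    adj = _IONIC_DECOY if decoy else _IONIC_ADJ
    species = species.upper()
    r_cat = tables.radius(species)
    r_o = tables.radius("O")
    leg = adj + r_cat + r_o
    ion = b.residue(species, "I", inum, "ion")
    cat = np.array([0.0, 0.0, 0.0])
    b.atom(ion, species, species.capitalize(), cat)
    half = 1.085
    dx = np.sqrt(_CARBOXYL_CO ** 2 - half ** 2)

    glu = b.residue("GLU", "A", rnum, "receptor")
    mg = cat - np.array([leg, 0.0, 0.0])
    b.atom(glu, "CD", "C", mg - np.array([dx, 0.0, 0.0]))
    b.atom(glu, "OE1", "O", mg + np.array([0.0, half, 0.0]))
    b.atom(glu, "OE2", "O", mg - np.array([0.0, half, 0.0]))
    gcu = b.residue("GCU", "B", lnum, "ligand")
    ml = cat + np.array([leg, 0.0, 0.0])
    b.atom(gcu, "C6", "C", ml + np.array([dx, 0.0, 0.0]))
    b.atom(gcu, "O6A", "O", ml + np.array([0.0, half, 0.0]))
    b.atom(gcu, "O6B", "O", ml - np.array([0.0, half, 0.0]))
    for res in (ion, glu, gcu):
        assign_protonation(res)
    return [glu, gcu, ion]


def _plant_hydrophobic(b, rnum, lnum, decoy=False):
    """ALA methyl against the NAG acetyl methyl."""
    d = _PHOBIC_DECOY if decoy else _PHOBIC_D
    ala = b.residue("ALA", "A", rnum, "receptor")
    cb = np.array([0.0, 0.0, 0.0])
    b.atom(ala, "CB", "C", cb)
    c8 = cb + np.array([d, 0.0, 0.0])
    for i, h in enumerate(_methyl_hydrogens(cb, c8), start=1):
        b.atom(ala, f"HB{i}", "H", h)
    nag = b.residue("NAG", "B", lnum, "ligand")
    b.atom(nag, "C8", "C", c8)
    for i, h in enumerate(_methyl_hydrogens(c8, cb), start=1):
        b.atom(nag, f"H8{i}", "H", h)
    return [ala, nag]


_GRID_SPACING = 14.0  # Å between motif sites; events never interact


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_planted_complex(n_hbond: int = 1, n_water_bridge: int = 1,
                         n_ionic: int = 1, n_cation_bridge: int = 1,
                         cation_species: str = "CA", n_hydrophobic: int = 1,
                         n_decoys: int = 0, seed: int = 0,
                         tables: TypingTables | None = None,
                         rotate: bool = True) -> PlantedComplex:
    """Deterministic synthetic complex with exactly known contacts.

    Each event sits in its own cell of a coarse 3D grid (14 Å spacing)
    under an optional random rigid rotation, so detector criteria are
    satisfied (or, for decoys, violated) with the stated margins and
    events cannot interact.  Decoys cycle through the five types.
    """
    for n in (n_hbond, n_water_bridge, n_ionic, n_cation_bridge,
              n_hydrophobic, n_decoys):
        if n < 0:
            raise ValueError("planted counts must be non-negative")
    tables = tables or TypingTables()
    rng = np.random.default_rng(seed)
    b = _Builder()
    jobs: list[tuple[str, bool]] = (
        [("hbond", False)] * n_hbond
        + [("water_bridge", False)] * n_water_bridge
        + [("ionic", False)] * n_ionic
        + [("cation_bridge", False)] * n_cation_bridge
        + [("hydrophobic", False)] * n_hydrophobic
    )
    decoy_cycle = ["hbond", "water_bridge", "ionic", "cation_bridge",
                   "hydrophobic"]
    jobs += [(decoy_cycle[i % 5], True) for i in range(n_decoys)]

    side = max(int(np.ceil(len(jobs) ** (1 / 3))), 1)
    if side > 12:
        raise ValueError("too many events for the placement grid")
    inventory = {k: 0 for k in ("hbond", "water_bridge", "ionic",
                                "cation_bridge", "hydrophobic")}
    participants: dict[str, list] = {k: [] for k in inventory}
    rnum, lnum, wnum, inum = 1, 1, 1, 1
    for idx, (kind, decoy) in enumerate(jobs):
        cell = np.array([idx % side, (idx // side) % side,
                         idx // (side * side)], dtype=float) * _GRID_SPACING
        before = len(b.residues)
        if kind == "hbond":
            made = _plant_hbond(b, rnum, lnum, decoy)
            rnum += 1; lnum += 1
        elif kind == "water_bridge":
            made = _plant_water_bridge(b, rnum, lnum, wnum, decoy)
            rnum += 1; lnum += 1; wnum += 1
        elif kind == "ionic":
            made = _plant_ionic(b, rnum, lnum, tables, decoy)
            rnum += 1; lnum += 1
        elif kind == "cation_bridge":
            made = _plant_cation_bridge(b, rnum, lnum, inum, cation_species,
                                        tables, decoy)
            rnum += 1; lnum += 1; inum += 1
        else:
            made = _plant_hydrophobic(b, rnum, lnum, decoy)
            rnum += 1; lnum += 1
        rot = _random_rotation(rng) if rotate else np.eye(3)
        for res in b.residues[before:]:
            for a in res.atoms:
                a.coord = rot @ a.coord + cell
        if not decoy:
            inventory[kind] += 1
            participants[kind].append(tuple(r.key for r in made))

    system = MolecularSystem(b.residues)
    return PlantedComplex(
        system=system,
        inventory=inventory,
        participants=participants,
        params=dict(seed=seed, n_decoys=n_decoys, cation_species=cation_species,
                    rotate=rotate),
    )


def make_random_hbond_sites(n_sites: int, seed: int = 0,
                            spacing: float = 15.0,
                            d_range: tuple[float, float] = (1.5, 3.5)
                            ) -> tuple[MolecularSystem, list[dict]]:
    """``n_sites`` isolated donor-H···acceptor-X geometries, randomized.

    Each site is a serine-like O-H donor and a sugar-like acceptor
    oxygen with one attached carbon, placed on a coarse grid (sites
    ``spacing`` Å apart, so inter-site hydrogen bonds are impossible
    for any spacing > 2.6 Å + fragment extent).  Per site, the
    hydrogen-acceptor distance is uniform over ``d_range`` and both
    criterion angles (donor-H-acceptor, H-acceptor-X) uniform over
    [0°, 180°], in a uniformly random orientation.  Returns the system
    and one parameter record per site (d, theta_dha, theta_hax).
    """
    rng = np.random.default_rng(seed)
    b = _Builder()
    side = max(int(np.ceil(n_sites ** (1 / 3))), 1)
    params = []
    for i in range(n_sites):
        cell = np.array([i % side, (i // side) % side,
                         i // (side * side)], dtype=float) * spacing
        d = rng.uniform(*d_range)
        t_dha = rng.uniform(0.0, 180.0)
        t_hax = rng.uniform(0.0, 180.0)
        # random orthonormal frame
        u = rng.normal(size=3); u /= np.linalg.norm(u)
        w = np.cross(u, rng.normal(size=3)); w /= np.linalg.norm(w)
        h = cell
        donor = h + _OH * u                      # H->D direction is u
        t = np.radians(t_dha)
        t_hat = np.cos(t) * u + np.sin(t) * w    # H->A direction
        acc = h + d * t_hat
        s = np.cross(t_hat, u)
        if np.linalg.norm(s) < 1e-9:             # collinear: any perp
            s = np.cross(t_hat, w)
        s /= np.linalg.norm(s)
        tx = np.radians(t_hax)
        x_dir = np.cos(tx) * (-t_hat) + np.sin(tx) * s  # A->X direction
        x = acc + _CO * x_dir
        ser = b.residue("SER", "A", i + 1, "receptor")
        b.atom(ser, "OG", "O", donor)
        b.atom(ser, "HG", "H", h)
        gcu = b.residue("GCU", "B", i + 1, "ligand")
        b.atom(gcu, "O2", "O", acc)
        b.atom(gcu, "C2", "C", x)
        params.append(dict(site=i, d=d, theta_dha=t_dha, theta_hax=t_hax))
    return MolecularSystem(b.residues), params


def make_trajectory(base: PlantedComplex | MolecularSystem, n_frames: int,
                    jitter_sd: float = 0.0, seed: int = 0,
                    frame_dt: float = 1.0) -> MolecularSystem:
    """Gaussian-jitter pseudo-trajectory from a base system.

    Every frame (including the first) gets independent isotropic
    Gaussian displacements of standard deviation ``jitter_sd`` Å per
    coordinate; with ``jitter_sd`` at most a quarter of the smallest
    criterion margin, planted counts survive in ≥95% of frames.  Frame
    times are ``index * frame_dt`` ns.  Deterministic given the seed.
    """
    system = base.system if isinstance(base, PlantedComplex) else base
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    residues = copy.deepcopy(system.residues)
    base_coords = system.frames[0].coords
    frames = []
    for i in range(n_frames):
        noise = (rng.normal(0.0, jitter_sd, size=base_coords.shape)
                 if jitter_sd > 0 else 0.0)
        frames.append(Frame(i, base_coords + noise, time=i * frame_dt))
    return MolecularSystem(residues, frames)
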