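"""Independent brute-force reference implementations of the detectors.

Everything here is written as plain double/triple loops straight from
the criteria definitions, sharing no code path with the package
detectors (only the domain types are reused as data carriers).  Used
to check detector output set-for-set on randomized frames.
"""

from __future__ import annotations

import math

import numpy as np


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _angle_deg(p1, p2, p3):
    v1 = np.asarray(p1) - np.asarray(p2)
    v2 = np.asarray(p3) - np.asarray(p2)
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _ramp(alpha, t1, t2):
    if alpha <= t1:
        return 0.0
    if alpha > t2:
        return 1.0
    return (alpha - t1) / (t2 - t1)


def _residue_neighbors(atom, frame=None):
    """Covalent neighbours from base coordinates (frame-independent)."""
    out = []
    p0 = atom.coord
    for other in atom.residue.atoms:
        if other is atom:
            continue
        d = _dist(p0, other.coord)
        if atom.element == "H" or other.element == "H":
            if atom.element == "H" and other.element == "H":
                continue
            if d <= 1.2:
                out.append(other)
        elif d <= 1.85:
            out.append(other)
    return out


def oracle_hbond_energy(d, s1, s2):
    return max(25.0 * (2.6 - max(d, 2.1)) / 0.5, 0.0) * s1 * s2


def oracle_hbonds(frame, groupA, groupB, threshold=6.25):
    """Set of (donor serial, hydrogen serial, acceptor serial, energy)."""
    found = set()
    for donors, acceptors in ((groupA, groupB), (groupB, groupA)):
        for heavy in donors:
            if heavy.element not in ("N", "O"):
                continue
            for h in _residue_neighbors(heavy, frame):
                if h.element != "H":
                    continue
                for acc in acceptors:
                    if acc.element not in ("N", "O"):
                        continue
                    d = _dist(frame.coords[h.index], frame.coords[acc.index])
                    a1 = _angle_deg(frame.coords[heavy.index],
                                    frame.coords[h.index],
                                    frame.coords[acc.index])
                    s1 = _ramp(a1, 75, 85)
                    xs = [x for x in _residue_neighbors(acc, frame) if x is not h]
                    if not xs:
                        s2 = 1.0
                    else:
                        s2 = max(
                            _ramp(_angle_deg(frame.coords[h.index],
                                             frame.coords[acc.index],
                                             frame.coords[x.index]),
                                  *((75, 85) if x.element == "H" else (85, 95)))
                            for x in xs)
                    e = oracle_hbond_energy(d, s1, s2)
                    if e > threshold:
                        found.add((heavy.serial, h.serial, acc.serial,
                                   round(e, 9)))
    return found


def oracle_water_bridges(frame, system, cutoff=3.0):
    """Set of (water key, receptor acceptor serial, ligand acceptor serial)."""
    rec = [a for a in system.atoms_with_role("receptor")
           if a.element in ("N", "O")]
    lig = [a for a in system.atoms_with_role("ligand")
           if a.element in ("N", "O")]
    found = set()
    for water in system.residues_with_role("water"):
        hs = [a for a in water.atoms if a.element == "H"]
        for ra in rec:
            for la in lig:
                ok = False
                for h_r, h_l in ((hs[0], hs[1]), (hs[1], hs[0])):
                    d_r = _dist(frame.coords[h_r.index], frame.coords[ra.index])
                    d_l = _dist(frame.coords[h_l.index], frame.coords[la.index])
                    if d_r <= cutoff and d_l <= cutoff:
                        ok = True
                if ok:
                    found.add((water.key, ra.serial, la.serial))
    return found


_ION_Q = {"NA": 1, "K": 1, "MG": 2, "CA": 2, "CL": -1}


def _oracle_centers(system, frame):
    """(residue key, role, position, charge, radius element) tuples."""
    out = []
    for res in system.residues:
        name = res.name.upper()
        if res.role == "ion" and name in _ION_Q:
            a = res.atoms[0]
            out.append((res.key, "ion", frame.coords[a.index], _ION_Q[name], name))
        elif name == "LYS" and res.has_atom("NZ"):
            out.append((res.key, res.role, frame.coords[res.atom("NZ").index],
                        1, "N"))
        elif name == "ARG" and res.has_atom("CZ"):
            out.append((res.key, res.role, frame.coords[res.atom("CZ").index],
                        1, "C"))
        elif name in ("ASP", "GLU", "GCU"):
            pair = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
                    "GCU": ("O6A", "O6B")}[name]
            if res.has_atom(pair[0]) and res.has_atom(pair[1]):
                p = (frame.coords[res.atom(pair[0]).index]
                     + frame.coords[res.atom(pair[1]).index]) / 2
                out.append((res.key, res.role, p, -1, "O"))
    return out


def oracle_ionic(frame, system, radii, lo=0.0, hi=1.5):
    """Set of (positive key, negative key, pairing)."""
    centers = _oracle_centers(system, frame)
    found = set()
    for i, (k1, role1, p1, q1, e1) in enumerate(centers):
        for k2, role2, p2, q2, e2 in centers[i + 1:]:
            if q1 * q2 >= 0:
                continue
            pairing = {frozenset(("receptor", "ligand")): "receptor-ligand",
                       frozenset(("ion", "receptor")): "ion-receptor",
                       frozenset(("ion", "ligand")): "ion-ligand",
                       }.get(frozenset((role1, role2)))
            if pairing is None:
                continue
            adj = _dist(p1, p2) - radii[e1] - radii[e2]
            if lo <= adj <= hi:
                pos, neg = ((k1, k2) if q1 > 0 else (k2, k1))
                found.add((pos, neg, pairing))
    return found


def oracle_cation_bridges(frame, system, radii, species=("CA", "MG")):
    """Set of (cation key, receptor centre key, ligand centre key)."""
    ionic = oracle_ionic(frame, system, radii)
    found = set()
    cations = [res for res in system.residues_with_role("ion")
               if res.name.upper() in species and _ION_Q.get(res.name.upper(), 0) > 0]
    for cat in cations:
        recs = [neg for pos, neg, pr in ionic
                if pr == "ion-receptor" and pos == cat.key]
        ligs = [neg for pos, neg, pr in ionic
                if pr == "ion-ligand" and pos == cat.key]
        for r in recs:
            for l in ligs:
                found.add((cat.key, r, l))
    return found


_RING = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}

_AA = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}


def _oracle_carbon_class(atom, frame):
    res = atom.residue
    if atom.element != "C":
        return "none"
    if res.name.upper() in _AA and atom.name == "CA" and res.name.upper() != "GLY":
        return "none"
    nbs = _residue_neighbors(atom, frame)
    n_h = sum(1 for n in nbs if n.element == "H")
    n_c = sum(1 for n in nbs if n.element == "C")
    if atom.name in _RING.get(res.name.upper(), set()) and n_h >= 1:
        return "aromatic-CH"
    if n_h == 3:
        return "CH3"
    if n_h == 2 or (n_h == 1 and n_c == 3):
        return "CH2/CH"
    return "none"


def oracle_hydrophobic(frame, system, cutoff=4.5):
    """Set of (receptor carbon serial, ligand carbon serial)."""
    found = set()
    for a in system.atoms_with_role("receptor"):
        if _oracle_carbon_class(a, frame) == "none":
            continue
        for b in system.atoms_with_role("ligand"):
            if _oracle_carbon_class(b, frame) == "none":
                continue
            if _dist(frame.coords[a.index], frame.coords[b.index]) <= cutoff:
                found.add((a.serial, b.serial))
    return found
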