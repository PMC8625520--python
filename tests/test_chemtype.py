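"""Protonation, donor/acceptor perception, hydrophobic classes,
charge centres and the hyaluronate oxygen-class map."""

import numpy as np
import pytest

from glycofp import MolecularSystem
from glycofp.chemtype import (DEFAULT_OXYGEN_CLASS_MAP, OXYGEN_CLASSES,
                              TypingTables, TypingError, assign_oxygen_classes,
                              assign_protonation, charge_center,
                              classify_hydrophobic_carbons,
                              find_donors_acceptors)
from glycofp.structure import Atom, Residue
from glycofp.synthetic import _Builder, make_water


def _residue(name, atom_spec, role="receptor"):
    res = Residue(name, "A", 1, role=role)
    for i, (aname, element, pos) in enumerate(atom_spec, start=1):
        res.atoms.append(Atom(i, aname, element, np.asarray(pos, float)))
    for a in res.atoms:
        a.residue = res
    return res


GLU_SIDE = _residue("GLU", [
    ("CG", "C", (0, 0, 0)),
    ("CD", "C", (1.52, 0, 0)),
    ("OE1", "O", (2.14, 1.08, 0)),
    ("OE2", "O", (2.14, -1.08, 0)),
])

LYS_SIDE = _residue("LYS", [
    ("CE", "C", (0, 0, 0)),
    ("NZ", "N", (1.47, 0, 0)),
    ("HZ1", "H", (1.80, 0.95, 0)),
])


@pytest.mark.parametrize("residue, atom, charge", [
    (GLU_SIDE, "OE2", -1),
    (LYS_SIDE, "NZ", +1),
])
def test_sidechain_charges_at_ph74(residue, atom, charge):
    charges = assign_protonation(residue, pH=7.4)
    assert charges[atom] == charge
    assert sum(charges.values()) == charge


def test_water_and_ions_protonation():
    b = _Builder()
    water = make_water(b, "W", 1, np.zeros(3), np.array([1.0, 0, 0]))
    assert set(assign_protonation(water).values()) == {0}
    ca = _residue("CA", [("CA", "Ca", (0, 0, 0))], role="ion")
    assert assign_protonation(ca)["CA"] == 2
    with pytest.raises(TypingError):
        assign_protonation(_residue("XXX", [("X1", "C", (0, 0, 0))]))


def test_his_neutral_by_default_protonated_on_switch():
    his = _residue("HIS", [
        ("CG", "C", (0, 0, 0)),
        ("ND1", "N", (1.0, 1.0, 0)),
        ("CE1", "C", (2.2, 0.7, 0)),
        ("NE2", "N", (2.2, -0.7, 0)),
        ("CD2", "C", (1.0, -1.0, 0)),
    ])
    assert sum(assign_protonation(his).values()) == 0
    tables = TypingTables(his_protonated=True)
    assert sum(assign_protonation(his, tables=tables).values()) == 1
    center = charge_center(his, tables)
    np.testing.assert_allclose(
        center.position, (his.atom("ND1").coord + his.atom("NE2").coord) / 2)
    assert center.charge == +1


def test_water_donor_acceptor_topology():
    b = _Builder()
    water = make_water(b, "W", 1, np.zeros(3), np.array([1.0, 0, 0]))
    water.role = "water"
    system = MolecularSystem([water])
    donor_pairs, acceptors = find_donors_acceptors(system, roles=("water",))
    assert len(acceptors) == 1 and acceptors[0].element == "O"
    assert len(donor_pairs) == 2
    assert {h.element for _, h in donor_pairs} == {"H"}


def test_hydroxyl_and_amide_both_donor_and_acceptor(disaccharide_system):
    donor_pairs, acceptors = find_donors_acceptors(
        disaccharide_system, roles=("ligand",))
    donors = {(d.residue.name, d.name) for d, _ in donor_pairs}
    acceptor_names = {(a.residue.name, a.name) for a in acceptors}
    # hydroxyl oxygen: both roles
    assert ("GCU", "O2") in donors and ("GCU", "O2") in acceptor_names
    # acetamido nitrogen: both roles
    assert ("NAG", "N2") in donors and ("NAG", "N2") in acceptor_names
    # carboxylate and ring oxygens never donate
    assert ("GCU", "O6A") not in donors and ("GCU", "O5") not in donors
    assert all(d.element in ("N", "O") for d, _ in donor_pairs)


def test_missing_hydrogens_error():
    bare = _residue("GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.45, 0, 0)),
                            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (3.2, 1.5, 0))])
    bare.role = "receptor"
    system = MolecularSystem([bare])
    from glycofp.chemtype import MissingHydrogensError
    with pytest.raises(MissingHydrogensError):
        find_donors_acceptors(system, roles=("receptor",))


def _ala():
    # minimal ALA with explicit hydrogens and correct covalent geometry
    return _residue("ALA", [
        ("N", "N", (-1.45, 0, 0)), ("H", "H", (-1.80, 0.94, 0)),
        ("CA", "C", (0, 0, 0)), ("HA", "H", (0, 0.51, 0.96)),
        ("CB", "C", (0, -1.07, -1.08)),
        ("HB1", "H", (0.89, -1.70, -1.08)),
        ("HB2", "H", (-0.89, -1.70, -1.08)),
        ("HB3", "H", (0, -0.60, -2.06)),
        ("C", "C", (1.52, 0, 0)), ("O", "O", (2.12, 1.07, 0)),
    ])


def _gly():
    return _residue("GLY", [
        ("N", "N", (-1.45, 0, 0)), ("H", "H", (-1.80, 0.94, 0)),
        ("CA", "C", (0, 0, 0)),
        ("HA2", "H", (0, 0.51, 0.96)), ("HA3", "H", (0, 0.51, -0.96)),
        ("C", "C", (1.52, 0, 0)), ("O", "O", (2.12, 1.07, 0)),
    ])


def _phe_fragment():
    # CB + aromatic ring with ring hydrogens, idealised hexagon
    atoms = [("CB", "C", (0, 0, 0)), ("HB2", "H", (-0.63, 0.89, 0)),
             ("HB3", "H", (-0.63, -0.89, 0))]
    center = np.array([2.91, 0, 0])  # CG then sits 1.52 Å from CB
    ring = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for k, name in enumerate(ring):
        t = np.radians(180 + 60 * k)
        pos = center + 1.39 * np.array([np.cos(t), np.sin(t), 0])
        atoms.append((name, "C", tuple(pos)))
        if name != "CG":
            h = center + 2.47 * np.array([np.cos(t), np.sin(t), 0])
            atoms.append((f"H{name[1:]}", "H", tuple(h)))
    return _residue("PHE", atoms)


def test_hydrophobic_classes():
    ala = _ala()
    classes = classify_hydrophobic_carbons(ala)
    assert classes["CB"] == "CH3"
    assert classes["CA"] == "none"          # alpha carbon excluded
    assert classes["C"] == "none"           # carbonyl carbon: no hydrogens
    gly = _gly()
    assert classify_hydrophobic_carbons(gly)["CA"] == "CH2/CH"  # Gly exception
    phe = _phe_fragment()
    pclasses = classify_hydrophobic_carbons(phe)
    assert pclasses["CD1"] == "aromatic-CH"
    assert pclasses["CG"] == "none"         # ring carbon without hydrogen
    assert pclasses["CB"] == "CH2/CH"


def test_classification_total_over_carbons(disaccharide_system):
    valid = {"CH3", "CH2/CH", "aromatic-CH", "none"}
    for res in disaccharide_system.residues:
        classes = classify_hydrophobic_carbons(res)
        carbons = [a.name for a in res.atoms if a.element == "C"]
        assert set(classes) == set(carbons)
        assert set(classes.values()) <= valid
    # the acetyl methyl of NAG is the only CH3 in the disaccharide
    nag = disaccharide_system.residues_with_role("ligand")[1]
    assert classify_hydrophobic_carbons(nag)["C8"] == "CH3"


def test_charge_centers():
    lys_center = charge_center(LYS_SIDE)
    assert lys_center.charge == +1 and lys_center.atoms[0].name == "NZ"
    glu_center = charge_center(GLU_SIDE)
    np.testing.assert_allclose(glu_center.position, [2.14, 0, 0])
    assert glu_center.charge == -1 and glu_center.radius_element == "O"
    ca = _residue("CA", [("CA", "Ca", (1, 2, 3))], role="ion")
    center = charge_center(ca)
    assert center.charge == +2
    np.testing.assert_allclose(center.position, [1, 2, 3])
    with pytest.raises(TypingError):
        charge_center(_ala())


def test_oxygen_class_map_totality(disaccharide_system):
    ligand = disaccharide_system.residues_with_role("ligand")
    classes = assign_oxygen_classes(ligand, strict=True)
    n_or_o = [a for r in ligand for a in r.atoms if a.element in ("N", "O")]
    assert set(classes) == {a.index for a in n_or_o}
    assert set(classes.values()) <= set(OXYGEN_CLASSES)
    # carboxylate oxygens share one class; amide nitrogen is class N
    gcu, nag = ligand
    assert classes[gcu.atom("O6A").index] == classes[gcu.atom("O6B").index]
    assert classes[nag.atom("N2").index] == "N"
    # hydroxyl-bearing classes follow the documented convention
    assert classes[gcu.atom("O1").index] == "O1"
    assert classes[nag.atom("O6").index] == "O10"


def test_strict_map_rejects_unmapped_atom():
    odd = _residue("GCU", [("O99", "O", (0, 0, 0))], role="ligand")
    with pytest.raises(TypingError):
        assign_oxygen_classes([odd], strict=True)
    lenient = assign_oxygen_classes([odd], strict=False)
    assert list(lenient.values()) == ["?"]


def test_total_charge_bookkeeping(planted_one_each):
    system = planted_one_each.system
    for res in system.residues:
        assign_protonation(res)
    total = sum(a.formal_charge for a in system.atoms)
    # LYS(+1)+GCU(-1) ionic pair, GLU(-1)+Ca(+2)+GCU(-1) bridge motif: sum 0
    assert total == 0
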