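"""Water bridges, ionic contacts, cation bridges, hydrophobic contacts."""

import numpy as np
import pytest

from glycofp import (MolecularSystem, detect_cation_bridges,
                     detect_hydrophobic_contacts, detect_ionic_contacts,
                     detect_water_bridges)
from glycofp.chemtype import MissingHydrogensError, TypingTables
from glycofp.structure import Atom, Frame, Residue
from glycofp.synthetic import (_Builder, _plant_cation_bridge, _plant_ionic,
                               _plant_water_bridge, make_planted_complex)
from oracles import (oracle_cation_bridges, oracle_hydrophobic, oracle_ionic,
                     oracle_water_bridges)

TABLES = TypingTables()


def _bridge_system(leg=2.8):
    b = _Builder()
    _plant_water_bridge(b, 1, 1, 1, decoy=False)
    system = MolecularSystem(b.residues)
    if leg != 2.8:
        # translate the water rigidly so the ligand leg becomes `leg`
        t = np.radians(104.5)
        u2 = np.array([-np.cos(t), np.sin(t), 0.0])
        water = system.residues_with_role("water")[0]
        shift = (2.8 - leg) * u2
        for a in water.atoms:
            system.frames[0].coords[a.index] += shift
    return system


def test_planted_water_bridge_detected():
    system = _bridge_system()
    bridges = detect_water_bridges(system.frames[0], system)
    assert len(bridges) == 1
    wb = bridges[0]
    assert wb.receptor_acceptor.name == "OD1"
    assert wb.ligand_acceptor.name == "O7"
    assert wb.dist_receptor == pytest.approx(2.8, abs=1e-9)
    assert wb.dist_ligand == pytest.approx(2.8, abs=1e-9)


def test_bridge_threshold_boundary():
    # one leg beyond 3.0 Å kills the bridge; at exactly 3.0 it survives
    assert detect_water_bridges(_bridge_system(3.2).frames[0],
                                _bridge_system(3.2)) == []
    at_limit = _bridge_system(3.0)
    assert len(detect_water_bridges(at_limit.frames[0], at_limit)) == 1


def test_bridge_sharpness_by_bisection():
    """Rigid translation scan: the bridge disappears exactly when the
    stretched leg crosses 3.0 Å (bisection to 1e-6 Å)."""
    def fires(leg):
        system = _bridge_system(leg)
        return len(detect_water_bridges(system.frames[0], system)) > 0

    lo, hi = 2.8, 3.5
    assert fires(lo) and not fires(hi)
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            lo = mid
        else:
            hi = mid
    assert lo == pytest.approx(3.0, abs=1e-6)


def test_water_free_frame_empty(disaccharide_system):
    assert detect_water_bridges(disaccharide_system.frames[0],
                                disaccharide_system) == []


def test_water_without_hydrogens_raises():
    res = Residue("HOH", "W", 1, role="water")
    res.atoms.append(Atom(1, "O", "O", np.zeros(3)))
    rec = Residue("ASN", "A", 1, role="receptor")
    rec.atoms.append(Atom(2, "OD1", "O", np.array([2.0, 0, 0])))
    lig = Residue("NAG", "B", 1, role="ligand")
    lig.atoms.append(Atom(3, "O7", "O", np.array([-2.0, 0, 0])))
    system = MolecularSystem([res, rec, lig])
    with pytest.raises(MissingHydrogensError):
        detect_water_bridges(system.frames[0], system)


def _ionic_system(adjusted):
    b = _Builder()
    _plant_ionic(b, 1, 1, TABLES, decoy=False)
    system = MolecularSystem(b.residues)
    delta = adjusted - 0.75
    gcu = system.residues_with_role("ligand")[0]
    # planted along -x from NZ: move further out by delta
    for a in gcu.atoms:
        system.frames[0].coords[a.index] += np.array([-delta, 0.0, 0.0])
    return system


def test_ionic_contact_adjusted_distance_range():
    # worked example: raw 4.2 Å, radii 1.75 + 1.70 -> adjusted 0.75
    system = _ionic_system(0.75)
    contacts = detect_ionic_contacts(system.frames[0], system)
    assert len(contacts) == 1
    ic = contacts[0]
    assert ic.pairing == "receptor-ligand"
    assert ic.raw_distance == pytest.approx(4.2, abs=1e-9)
    assert ic.adjusted_distance == pytest.approx(0.75, abs=1e-9)
    assert ic.positive.residue.name == "LYS" and ic.negative.residue.name == "GCU"
    # 1.45 still inside, 1.6 outside
    inside = _ionic_system(1.45)
    assert len(detect_ionic_contacts(inside.frames[0], inside)) == 1
    outside = _ionic_system(1.6)
    assert detect_ionic_contacts(outside.frames[0], outside) == []


def test_ionic_range_boundaries_inclusive():
    for adj, expected in [(0.0, 1), (-0.05, 0), (1.5, 1), (1.500001, 0)]:
        system = _ionic_system(adj)
        got = detect_ionic_contacts(system.frames[0], system)
        assert len(got) == expected, f"adjusted={adj}"


def test_ionic_upper_bound_by_bisection():
    def fires(adj):
        system = _ionic_system(adj)
        return len(detect_ionic_contacts(system.frames[0], system)) > 0

    lo, hi = 0.75, 2.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            lo = mid
        else:
            hi = mid
    assert lo == pytest.approx(1.5, abs=1e-6)


def test_cations_only_system_empty():
    res = Residue("NA", "I", 1, role="ion")
    res.atoms.append(Atom(1, "NA", "Na", np.zeros(3)))
    res2 = Residue("MG", "I", 2, role="ion")
    res2.atoms.append(Atom(2, "MG", "Mg", np.array([3.0, 0, 0])))
    system = MolecularSystem([res, res2])
    assert detect_ionic_contacts(system.frames[0], system) == []


def _bridge_motif_system(species="CA"):
    b = _Builder()
    _plant_cation_bridge(b, 1, 1, 1, species, TABLES, decoy=False)
    return MolecularSystem(b.residues)


def test_cation_bridge_detected_and_decomposes():
    system = _bridge_motif_system("CA")
    frame = system.frames[0]
    bridges = detect_cation_bridges(frame, system)
    assert len(bridges) == 1
    cb = bridges[0]
    assert cb.cation.residue.name == "CA" and cb.cation.charge == 2
    assert cb.receptor_center.residue.name == "GLU"
    assert cb.ligand_center.residue.name == "GCU"
    # bridge decomposition: both component ionic contacts exist
    ionic = detect_ionic_contacts(frame, system)
    pairings = sorted(c.pairing for c in ionic)
    assert pairings == ["ion-ligand", "ion-receptor"]
    assert all(c.positive.residue.key == cb.cation.residue.key for c in ionic)


def test_cation_in_range_of_ligand_only_is_no_bridge():
    system = _bridge_motif_system("CA")
    frame = system.frames[0]
    glu = system.residues_with_role("receptor")[0]
    for a in glu.atoms:
        frame.coords[a.index] += np.array([-5.0, 0.0, 0.0])
    assert detect_cation_bridges(frame, system) == []
    assert [c.pairing for c in detect_ionic_contacts(frame, system)] == ["ion-ligand"]


def test_two_receptor_centers_give_two_bridges():
    system = _bridge_motif_system("CA")
    # add a second GLU mirrored above the cation, also in range
    b_extra = Residue("GLU", "A", 2, role="receptor")
    leg = 0.75 + TABLES.radius("CA") + TABLES.radius("O")
    m = np.array([0.0, leg, 0.0])
    half, dx = 1.085, np.sqrt(1.25 ** 2 - 1.085 ** 2)
    serial = max(a.serial for a in system.atoms)
    for i, (nm, p) in enumerate([("CD", m + [0, dx, 0]),
                                 ("OE1", m + [half, 0, 0]),
                                 ("OE2", m - [half, 0, 0])], 1):
        b_extra.atoms.append(Atom(serial + i, nm, "O" if nm != "CD" else "C",
                                  np.asarray(p, float)))
    system2 = MolecularSystem(system.residues + [b_extra])
    bridges = detect_cation_bridges(system2.frames[0], system2)
    assert len(bridges) == 2
    assert {b.receptor_center.residue.number for b in bridges} == {1, 2}


def test_sodium_excluded_by_default_species_filter():
    system = _bridge_motif_system("NA")
    frame = system.frames[0]
    assert detect_cation_bridges(frame, system) == []
    assert len(detect_cation_bridges(frame, system, species=("NA",))) == 1


def test_hydrophobic_contact_and_cutoff():
    planted = make_planted_complex(0, 0, 0, 0, "CA", 1, 0, seed=5, rotate=False)
    system = planted.system
    contacts = detect_hydrophobic_contacts(system.frames[0], system)
    assert len(contacts) == 1
    hp = contacts[0]
    assert hp.class_a == "CH3" and hp.class_b == "CH3"
    assert hp.distance == pytest.approx(4.0, abs=1e-9)
    assert detect_hydrophobic_contacts(system.frames[0], system, cutoff=3.9) == []


def test_alpha_carbon_excluded_from_hydrophobic():
    ala = Residue("ALA", "A", 1, role="receptor")
    ala.atoms.append(Atom(1, "CA", "C", np.zeros(3)))
    ala.atoms.append(Atom(2, "HA", "H", np.array([0.0, 1.09, 0.0])))
    ala.atoms.append(Atom(3, "HA2", "H", np.array([0.0, -1.09, 0.0])))
    nag = Residue("NAG", "B", 1, role="ligand")
    c8 = np.array([3.5, 0.0, 0.0])
    nag.atoms.append(Atom(4, "C8", "C", c8))
    for i, d in enumerate([(1, 0.4, 0), (1, -0.4, 0.4), (1, 0, -0.55)], 5):
        u = np.asarray(d, float)
        nag.atoms.append(Atom(i, f"H8{i-4}", "H", c8 + 1.09 * u / np.linalg.norm(u)))
    system = MolecularSystem([ala, nag])
    assert detect_hydrophobic_contacts(system.frames[0], system) == []


def test_detector_oracle_equivalence_on_jittered_complexes():
    """All four geometric detectors agree with the brute-force oracles
    on randomly perturbed planted complexes."""
    from glycofp.synthetic import make_trajectory
    rng = np.random.default_rng(11)
    for seed in range(12):
        planted = make_planted_complex(2, 2, 2, 1, "MG" if seed % 2 else "CA",
                                       2, n_decoys=seed % 3, seed=seed)
        traj = make_trajectory(planted, 3, jitter_sd=0.25, seed=seed + 100)
        for frame in traj.frames:
            got_wb = {wb.key() for wb in detect_water_bridges(frame, traj)}
            assert got_wb == oracle_water_bridges(frame, traj)
            got_ic = {(c.positive.residue.key, c.negative.residue.key, c.pairing)
                      for c in detect_ionic_contacts(frame, traj)}
            assert got_ic == oracle_ionic(frame, traj, TABLES.hbond_radii)
            got_cb = {(b.cation.residue.key, b.receptor_center.residue.key,
                       b.ligand_center.residue.key)
                      for b in detect_cation_bridges(frame, traj)}
            assert got_cb == oracle_cation_bridges(frame, traj, TABLES.hbond_radii)
            got_hp = {(c.atom_a.serial, c.atom_b.serial)
                      for c in detect_hydrophobic_contacts(frame, traj)}
            assert got_hp == oracle_hydrophobic(frame, traj)
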