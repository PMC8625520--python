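"""Trajectory-level interaction fingerprints and complex rankings.

Per-frame contact lists are aggregated into: mean and total counts per
contact type over the analysis window (the equilibration-exclusion
window of the binding-energy trace, default: drop the first 40% of
frames), amino-acid-type × ligand-oxygen-class matrices for direct
hydrogen bonds and water bridges, per-amino-acid hydrophobic counts,
and the set of receptor subdomains touched by any contact.

Counts are reported both as window means and as window totals: the
per-frame mean answers "how many of this contact exist at a typical
equilibrated frame", the total feeds the class matrices, whose grand
total always reconciles with the raw contact lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemtype import (OXYGEN_CLASS_MAP_VERSION, OXYGEN_CLASSES, TypingTables,
                       assign_oxygen_classes)
from .contacts import (CationBridge, HydrophobicContact, IonicContact,
                       WaterBridge, detect_cation_bridges,
                       detect_hydrophobic_contacts, detect_ionic_contacts,
                       detect_water_bridges)
from .hbonds import HBondContact, detect_hbonds
from .structure import MolecularSystem
from .energy import BindingEnergyTrace, trace_statistics

__all__ = [
    "FrameContacts",
    "InteractionFingerprint",
    "SubdomainRanges",
    "DEFAULT_SUBDOMAINS",
    "analyze_frames",
    "accumulate",
    "residue_class_matrix",
    "contacted_subdomains",
    "rank_complexes",
]

CONTACT_TYPES = ("hbond", "water_bridge", "ionic", "cation_bridge",
                 "hydrophobic")


@dataclass
class FrameContacts:
    """All detected contacts of one frame."""

    frame_index: int
    hbonds: list[HBondContact] = field(default_factory=list)
    water_bridges: list[WaterBridge] = field(default_factory=list)
    ionic: list[IonicContact] = field(default_factory=list)
    cation_bridges: list[CationBridge] = field(default_factory=list)
    hydrophobic: list[HydrophobicContact] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "hbond": len(self.hbonds),
            "water_bridge": len(self.water_bridges),
            "ionic": len([c for c in self.ionic
                          if c.pairing == "receptor-ligand"]),
            "cation_bridge": len(self.cation_bridges),
            "hydrophobic": len(self.hydrophobic),
        }


def analyze_frames(system: MolecularSystem,
                   tables: TypingTables | None = None,
                   bridge_species=("CA", "MG")) -> list[FrameContacts]:
    """Run all five detectors on every frame of a system."""
    tables = tables or TypingTables()
    receptor = system.atoms_with_role("receptor")
    ligand = system.atoms_with_role("ligand")
    out = []
    for frame in system.frames:
        out.append(FrameContacts(
            frame_index=frame.index,
            hbonds=detect_hbonds(frame, receptor, ligand, tables),
            water_bridges=detect_water_bridges(frame, system, tables),
            ionic=detect_ionic_contacts(frame, system, tables),
            cation_bridges=detect_cation_bridges(frame, system,
                                                 bridge_species, tables),
            hydrophobic=detect_hydrophobic_contacts(frame, system,
                                                    tables=tables),
        ))
    return out


#: Albumin subdomain residue ranges (inclusive); residues 1-4 and
#: 570-585 of the 585-residue chain belong to no subdomain ("other").
DEFAULT_SUBDOMAINS: dict[str, tuple[int, int]] = {
    "IA": (5, 107), "IB": (108, 197), "IIA": (198, 296),
    "IIB": (297, 382), "IIIA": (383, 494), "IIIB": (495, 569),
}

SUBDOMAIN_ORDER = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB")


@dataclass
class SubdomainRanges:
    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SUBDOMAINS))

    def label(self, residue_number: int) -> str:
        for name, (lo, hi) in self.ranges.items():
            if lo <= residue_number <= hi:
                return name
        return "other"


@dataclass
class InteractionFingerprint:
    """Aggregated interaction profile of one trajectory."""

    frame_counts: pd.DataFrame          # frames × contact types
    window_mask: np.ndarray             # frames inside the analysis window
    mean_counts: pd.Series
    total_counts: pd.Series
    hbond_matrix: pd.DataFrame          # amino acid × oxygen class
    water_bridge_matrix: pd.DataFrame
    hydrophobic_by_residue: pd.Series   # amino-acid type -> count
    contact_residue_numbers: set[int]   # receptor residues in any contact
    map_version: str = OXYGEN_CLASS_MAP_VERSION


def _window_mask(n_frames: int, window: float | None) -> np.ndarray:
    frac = 0.4 if window is None else float(window)
    if not (0.0 <= frac < 1.0):
        raise ValueError("window fraction must lie in [0, 1)")
    t = np.arange(n_frames, dtype=float)
    if n_frames == 1:
        return np.array([True])
    start = frac * t[-1]
    return t >= start


def accumulate(per_frame: list[FrameContacts], system: MolecularSystem,
               window: float | None = None,
               strict_classes: bool = True) -> InteractionFingerprint:
    """Aggregate per-frame contact lists into a fingerprint.

    ``window`` is the excluded leading fraction of frames (default
    0.4, the equilibration exclusion); the window is closed on the
    left, matching :func:`glycofp.energy.trace_statistics`.
    """
    if not per_frame:
        raise ValueError("no frames to accumulate")
    if len(per_frame) != system.n_frames:
        raise ValueError(
            f"{len(per_frame)} contact frames for a {system.n_frames}-frame system")
    mask = _window_mask(len(per_frame), window)
    counts = pd.DataFrame([fc.counts() for fc in per_frame],
                          index=[fc.frame_index for fc in per_frame])
    windowed = counts.loc[mask]
    if windowed.empty:
        raise ValueError("analysis window contains no frames")

    classes = assign_oxygen_classes(system.residues_with_role("ligand"),
                                    strict=strict_classes)
    aa_names = sorted({r.name for r in system.residues_with_role("receptor")})
    zeros = lambda: pd.DataFrame(0, index=aa_names, columns=list(OXYGEN_CLASSES))
    hb_m, wb_m = zeros(), zeros()
    phobic = pd.Series(0, index=aa_names, dtype=int)
    contact_residues: set[int] = set()

    for fc, inside in zip(per_frame, mask):
        if not inside:
            continue
        for hb in fc.hbonds:
            rec, lig = ((hb.donor, hb.acceptor)
                        if hb.donor.residue.role == "receptor"
                        else (hb.acceptor, hb.donor))
            cls = classes.get(lig.index, "?")
            if cls != "?":
                hb_m.loc[rec.residue.name, cls] += 1
            contact_residues.add(rec.residue.number)
        for wb in fc.water_bridges:
            cls = classes.get(wb.ligand_acceptor.index, "?")
            if cls != "?":
                wb_m.loc[wb.receptor_acceptor.residue.name, cls] += 1
            contact_residues.add(wb.receptor_acceptor.residue.number)
        for ic in fc.ionic:
            if ic.pairing == "receptor-ligand":
                rec = (ic.positive if ic.positive.residue.role == "receptor"
                       else ic.negative)
                contact_residues.add(rec.residue.number)
        for cb in fc.cation_bridges:
            contact_residues.add(cb.receptor_center.residue.number)
        for hp in fc.hydrophobic:
            phobic[hp.atom_a.residue.name] += 1
            contact_residues.add(hp.atom_a.residue.number)

    return InteractionFingerprint(
        frame_counts=counts,
        window_mask=mask,
        mean_counts=windowed.mean(),
        total_counts=windowed.sum(),
        hbond_matrix=hb_m,
        water_bridge_matrix=wb_m,
        hydrophobic_by_residue=phobic,
        contact_residue_numbers=contact_residues,
    )


def contacts_table(per_frame: list[FrameContacts]) -> pd.DataFrame:
    """One row per detected contact across all frames (TSV-ready)."""
    rows = []
    for fc in per_frame:
        for hb in fc.hbonds:
            rows.append(dict(
                frame=fc.frame_index, type="hbond",
                receptor=f"{hb.donor.residue.name}{hb.donor.residue.number}"
                if hb.donor.residue.role == "receptor"
                else f"{hb.acceptor.residue.name}{hb.acceptor.residue.number}",
                detail=f"{hb.donor.name}-{hb.hydrogen.name}...{hb.acceptor.name}",
                distance=round(hb.dis_HA, 3), value=round(hb.energy, 3)))
        for wb in fc.water_bridges:
            rows.append(dict(
                frame=fc.frame_index, type="water_bridge",
                receptor=(f"{wb.receptor_acceptor.residue.name}"
                          f"{wb.receptor_acceptor.residue.number}"),
                detail=(f"{wb.receptor_acceptor.name}..HOH{wb.water.number}.."
                        f"{wb.ligand_acceptor.name}"),
                distance=round(max(wb.dist_receptor, wb.dist_ligand), 3),
                value=None))
        for ic in fc.ionic:
            rows.append(dict(
                frame=fc.frame_index, type="ionic",
                receptor=f"{ic.positive.label}|{ic.negative.label}",
                detail=ic.pairing, distance=round(ic.raw_distance, 3),
                value=round(ic.adjusted_distance, 3)))
        for cb in fc.cation_bridges:
            rows.append(dict(
                frame=fc.frame_index, type="cation_bridge",
                receptor=cb.receptor_center.label,
                detail=f"{cb.cation.label}|{cb.ligand_center.label}",
                distance=round(cb.adjusted_receptor, 3),
                value=round(cb.adjusted_ligand, 3)))
        for hp in fc.hydrophobic:
            rows.append(dict(
                frame=fc.frame_index, type="hydrophobic",
                receptor=f"{hp.atom_a.residue.name}{hp.atom_a.residue.number}",
                detail=f"{hp.atom_a.name}({hp.class_a})-{hp.atom_b.name}({hp.class_b})",
                distance=round(hp.distance, 3), value=None))
    columns = ["frame", "type", "receptor", "detail", "distance", "value"]
    return pd.DataFrame(rows, columns=columns)


def residue_class_matrix(fingerprint: InteractionFingerprint,
                         contact_type: str = "hbond") -> pd.DataFrame:
    """The amino-acid × oxygen-class matrix for hbond or water_bridge."""
    if contact_type == "hbond":
        return fingerprint.hbond_matrix
    if contact_type == "water_bridge":
        return fingerprint.water_bridge_matrix
    raise ValueError(f"no class matrix for contact type {contact_type!r}")


def contacted_subdomains(source, ranges: SubdomainRanges | None = None
                         ) -> list[str]:
    """Subdomain labels touched by at least one contact, canonical order.

    ``source`` is an :class:`InteractionFingerprint` or any iterable of
    receptor residue numbers.  Residues outside every range contribute
    the label ``other``, placed last.  Join with "-" for report output
    (e.g. ``IA-IB-IIIA-IIIB``).
    """
    ranges = ranges or SubdomainRanges()
    if isinstance(source, InteractionFingerprint):
        numbers = source.contact_residue_numbers
    else:
        numbers = set(source)
    labels = {ranges.label(n) for n in numbers}
    ordered = [s for s in SUBDOMAIN_ORDER if s in labels]
    if "other" in labels:
        ordered.append("other")
    return ordered


def rank_complexes(traces: list[BindingEnergyTrace],
                   window: float | None = None
                   ) -> list[tuple[int, str, float, float]]:
    """Order complexes by decreasing windowed mean binding energy.

    Returns ``(input_index, label, mean, sd)`` tuples; positive mean =
    stronger binding, ties keep input order (stable sort).
    """
    if not traces:
        raise ValueError("need at least one trace")
    stats = [trace_statistics(tr, window) for tr in traces]
    order = sorted(range(len(traces)), key=lambda i: -stats[i][0])
    return [(i, traces[i].label, stats[i][0], stats[i][1]) for i in order]
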