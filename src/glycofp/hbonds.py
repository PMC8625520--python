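"""Geometric hydrogen-bond energy scoring and per-frame detection.

The hydrogen-bond energy (kJ/mol) of a donor–H···acceptor geometry is

    E_HB = 25 * (2.6 - max(d_HA, 2.1)) / 0.5 * s_DHA * s_HAX

where ``d_HA`` is the hydrogen–acceptor distance in Å and the two
``s`` factors are piecewise-linear angular weights in [0, 1]: one for
the donor–hydrogen–acceptor angle (measured at the hydrogen) and one
for the hydrogen–acceptor–X angle, X being an atom covalently attached
to the acceptor.  The energy is clamped at its 25 kJ/mol plateau for
d ≤ 2.1 Å and floors at 0 for d ≥ 2.6 Å.  A pair counts as a hydrogen
bond when E_HB is strictly greater than 6.25 kJ/mol.

Two θ tables drive the angular ramps: (85°, 95°) when the third atom
of the angle is a heavy atom and (75°, 85°) when it is a hydrogen.
The ramp used here increases with the angle — 0 at or below θ1, 1
above θ2 — so straighter bonds score higher and the piecewise limits
are continuous at θ2; the opposite (decreasing) orientation that a
literal reading of the source convention's ramp formula would give is
available behind ``ramp_decreasing=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chemtype import MissingHydrogensError, TypingTables, covalent_neighbors
from .structure import Atom, Frame

__all__ = [
    "AngularRamp",
    "HBondContact",
    "HEAVY_RAMP",
    "HYDROGEN_RAMP",
    "ENERGY_THRESHOLD",
    "angular_scaling",
    "hbond_energy",
    "detect_hbonds",
]

#: Detection threshold, kJ/mol; strictly "higher than".
ENERGY_THRESHOLD = 6.25

#: Maximum H···A distance at which E_HB can exceed the threshold with
#: both angular factors at 1: 25*(2.6-d)/0.5 > 6.25  =>  d < 2.475 Å.
#: Used only as a provably lossless neighbour-search prefilter.
PREFILTER_RADIUS = 2.475


@dataclass(frozen=True)
class AngularRamp:
    """Piecewise-linear angular weight with thresholds in degrees."""

    theta1: float
    theta2: float
    atom_kind: str = "heavy"

    def __post_init__(self):
        if not (0 < self.theta1 < self.theta2 <= 180):
            raise ValueError(f"invalid ramp thresholds ({self.theta1}, {self.theta2})")


HEAVY_RAMP = AngularRamp(85.0, 95.0, "heavy")
HYDROGEN_RAMP = AngularRamp(75.0, 85.0, "hydrogen")


def angular_scaling(alpha: float, ramp: AngularRamp,
                    decreasing: bool = False) -> float:
    """Angular weight s(α) in [0, 1] for an angle ``alpha`` in degrees.

    Increasing orientation (default): 0 for α ≤ θ1, (α−θ1)/(θ2−θ1) on
    (θ1, θ2], 1 above θ2.  With ``decreasing=True`` the ramp segment is
    (θ2−α)/(θ2−θ1), the literal printed form of the source convention.
    """
    if not (0.0 <= alpha <= 180.0):
        raise ValueError(f"angle {alpha} outside [0, 180] degrees")
    if alpha <= ramp.theta1:
        return 0.0
    if alpha > ramp.theta2:
        return 1.0
    if decreasing:
        return (ramp.theta2 - alpha) / (ramp.theta2 - ramp.theta1)
    return (alpha - ramp.theta1) / (ramp.theta2 - ramp.theta1)


def hbond_energy(dis_HA: float, s_DAH: float = 1.0, s_HAX: float = 1.0) -> float:
    """Hydrogen-bond energy in kJ/mol; see the module docstring."""
    if dis_HA <= 0:
        raise ValueError("hydrogen-acceptor distance must be positive")
    if not (0.0 <= s_DAH <= 1.0 and 0.0 <= s_HAX <= 1.0):
        raise ValueError("scaling factors must lie in [0, 1]")
    raw = 25.0 * (2.6 - max(dis_HA, 2.1)) / 0.5
    return max(raw, 0.0) * s_DAH * s_HAX


@dataclass
class HBondContact:
    """One detected hydrogen bond with its geometry and energy."""

    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    acceptor_attached: Atom | None
    dis_HA: float
    s_DAH: float
    s_HAX: float
    energy: float

    def key(self) -> tuple[int, int]:
        return (self.donor.serial, self.acceptor.serial)


def _angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 in degrees."""
    v1 = p1 - p2
    v2 = p3 - p2
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def score_hbond(frame: Frame, donor: Atom, hydrogen: Atom, acceptor: Atom,
                tables: TypingTables | None = None,
                decreasing_ramp: bool = False,
                neighbor_rule: str = "max") -> HBondContact:
    """Score one donor–H···acceptor candidate (no threshold applied).

    The donor–H–A angle is measured at the hydrogen vertex and weighted
    by the hydrogen θ table.  The H–A–X factor is evaluated for every
    covalent neighbour X of the acceptor — heavy θ table when X is a
    heavy atom, hydrogen table when X is a hydrogen — and combined with
    ``neighbor_rule`` ("max", the permissive default, or "min").  An
    acceptor without covalent neighbours gets s_HAX = 1.
    """
    c = frame.coords
    d_ha = float(np.linalg.norm(c[hydrogen.index] - c[acceptor.index]))
    a_dha = _angle(c[donor.index], c[hydrogen.index], c[acceptor.index])
    s_dah = angular_scaling(a_dha, HYDROGEN_RAMP, decreasing_ramp)
    # topology from base coordinates: constant across trajectory frames
    neighbors = [nb for nb in covalent_neighbors(acceptor) if nb is not hydrogen]
    if not neighbors:
        s_hax, attached = 1.0, None
    else:
        scored = []
        for nb in neighbors:
            ramp = HYDROGEN_RAMP if nb.element == "H" else HEAVY_RAMP
            a_hax = _angle(c[hydrogen.index], c[acceptor.index], c[nb.index])
            scored.append((angular_scaling(a_hax, ramp, decreasing_ramp), nb))
        pick = max if neighbor_rule == "max" else min
        s_hax, attached = pick(scored, key=lambda t: t[0])
    energy = hbond_energy(d_ha, s_dah, s_hax)
    return HBondContact(donor, hydrogen, acceptor, attached, d_ha,
                        s_dah, s_hax, energy)


def detect_hbonds(frame: Frame, groupA: list[Atom], groupB: list[Atom],
                  tables: TypingTables | None = None,
                  decreasing_ramp: bool = False,
                  neighbor_rule: str = "max") -> list[HBondContact]:
    """All hydrogen bonds between two disjoint atom groups in one frame.

    Donor hydrogens of each group are tested against N/O acceptors of
    the other (both directions); every pair with energy strictly above
    the threshold is kept — no best-per-hydrogen pruning.  Output is
    ordered by (donor serial, acceptor serial, hydrogen serial).
    """
    tables = tables or TypingTables()
    idsA = {a.index for a in groupA}
    idsB = {b.index for b in groupB}
    if idsA & idsB:
        raise ValueError("hydrogen-bond groups must be disjoint")

    has_no = any(a.element in ("N", "O") for a in groupA) and \
        any(a.element in ("N", "O") for a in groupB)
    if has_no and not any(a.element == "H" for a in list(groupA) + list(groupB)):
        raise MissingHydrogensError(
            "hydrogen-bond detection requires explicit hydrogens")

    contacts: list[HBondContact] = []
    for donors_side, acceptors_side in ((groupA, groupB), (groupB, groupA)):
        acceptors = [a for a in acceptors_side if a.element in ("N", "O")]
        donor_heavy = [a for a in donors_side if a.element in ("N", "O")]
        if not acceptors or not donor_heavy:
            continue
        donor_pairs = []
        for heavy in donor_heavy:
            for nb in covalent_neighbors(heavy):
                if nb.element == "H":
                    donor_pairs.append((heavy, nb))
        if not donor_pairs:
            continue
        h_coords = np.array([frame.coords[h.index] for _, h in donor_pairs])
        a_coords = np.array([frame.coords[a.index] for a in acceptors])
        tree = cKDTree(a_coords)
        hits = tree.query_ball_point(h_coords, r=PREFILTER_RADIUS)
        for (heavy, hyd), acc_ids in zip(donor_pairs, hits):
            for ai in acc_ids:
                contact = score_hbond(frame, heavy, hyd, acceptors[ai], tables,
                                      decreasing_ramp, neighbor_rule)
                if contact.energy > tables.hbond_energy_threshold:
                    contacts.append(contact)
    contacts.sort(key=lambda c: (c.donor.serial, c.acceptor.serial,
                                 c.hydrogen.serial))
    return contacts
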