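"""Binding-energy decomposition over trajectory frames.

The binding energy of a receptor–ligand complex in one frame is

    E_bind = E_pot1 + E_pot2 + E_sol1 + E_sol2 − (E_pot_comp + E_sol_comp)

where the subscripts 1/2 denote the receptor and ligand evaluated in
isolation and "comp" the complex; potential and solvation terms are in
kJ/mol.  High positive E_bind means high affinity: the cross terms that
stabilise the complex appear only in the "comp" terms, so attraction
lowers E_pot_comp below E_pot1 + E_pot2 and raises E_bind.

The energy backend is a contract (potential_energy / solvation_energy
over an atom set); the shipped :func:`reference_backend` is a
deliberately simple desk-scale model — 12-6 van der Waals plus Coulomb
with a distance-dependent dielectric and a solvent-accessible-surface-
area-proportional solvation term — adequate for algebra, limits and
sign conventions, not for force-field fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import biotite.structure as struc

from .structure import Atom, Frame, MolecularSystem

__all__ = [
    "EnergyComponents",
    "BindingEnergyTrace",
    "EnergyBackend",
    "binding_energy",
    "compute_components",
    "compute_trace",
    "reference_backend",
    "null_backend",
    "trace_statistics",
]

#: Coulomb constant, kJ mol^-1 Å e^-2.
COULOMB_KE = 1389.35457644382


@dataclass
class EnergyComponents:
    """The six terms of the binding-energy decomposition, kJ/mol."""

    E_pot1: float
    E_pot2: float
    E_sol1: float
    E_sol2: float
    E_pot_comp: float
    E_sol_comp: float

    def as_dict(self) -> dict[str, float]:
        return dict(E_pot1=self.E_pot1, E_pot2=self.E_pot2,
                    E_sol1=self.E_sol1, E_sol2=self.E_sol2,
                    E_pot_comp=self.E_pot_comp, E_sol_comp=self.E_sol_comp)


def binding_energy(components: EnergyComponents) -> float:
    """E_bind from the six components; positive = higher affinity."""
    vals = list(components.as_dict().values())
    if not all(np.isfinite(vals)):
        raise ValueError("energy components must be finite")
    return (components.E_pot1 + components.E_pot2
            + components.E_sol1 + components.E_sol2
            - (components.E_pot_comp + components.E_sol_comp))


@dataclass
class EnergyBackend:
    """Pluggable evaluator contract.

    Both callables take (atoms, frame) and return kJ/mol; they must be
    deterministic in the coordinates, and the potential term must be
    additive over non-interacting subsets.
    """

    potential_energy: Callable[[Sequence[Atom], Frame], float]
    solvation_energy: Callable[[Sequence[Atom], Frame], float]
    name: str = "custom"


def null_backend() -> EnergyBackend:
    """Backend returning 0 for everything (algebra checks)."""
    return EnergyBackend(lambda atoms, frame: 0.0,
                         lambda atoms, frame: 0.0, name="null")


# --- reference backend -----------------------------------------------------

#: Lennard-Jones parameters per element: sigma (Å), epsilon (kJ/mol).
#: Generic textbook-scale values; combined with Lorentz-Berthelot rules.
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.066), "C": (3.40, 0.360), "N": (3.25, 0.711),
    "O": (2.96, 0.880), "S": (3.55, 1.046), "P": (3.74, 0.836),
    "NA": (2.35, 0.200), "MG": (1.60, 3.700), "CA": (2.70, 0.500),
    "CL": (4.40, 0.420), "K": (3.30, 0.130),
}

#: Van der Waals radii (Å) for the SASA term.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "NA": 2.27, "MG": 1.73, "CA": 2.31, "CL": 1.75, "K": 2.75,
}

SASA_PROBE_RADIUS = 1.4   # Å, water probe
SASA_COEFFICIENT = 0.02   # kJ mol^-1 Å^-2, microscopic surface tension
DIELECTRIC_SLOPE = 4.0    # D(r) = 4 r, distance-dependent screening


def _lj_lookup(element: str, params) -> tuple[float, float]:
    key = element.upper()
    if key not in params:
        raise KeyError(f"no nonbonded parameters for element {element!r}")
    return params[key]


def _pair_potential(atoms: Sequence[Atom], frame: Frame, params) -> float:
    """Sum of LJ + screened Coulomb over inter-residue atom pairs.

    Intra-residue pairs are skipped: covalent chemistry is not
    modelled, and those terms cancel exactly in the binding-energy
    difference.
    """
    atoms = list(atoms)
    n = len(atoms)
    if n < 2:
        return 0.0
    coords = np.array([frame.coords[a.index] for a in atoms])
    sig = np.empty(n)
    eps = np.empty(n)
    q = np.empty(n)
    res_id = np.empty(n, dtype=int)
    res_keys: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        sig[i], eps[i] = _lj_lookup(a.element, params)
        q[i] = a.formal_charge
        res_id[i] = res_keys.setdefault(a.residue.key, len(res_keys))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    mask = res_id[iu[0]] != res_id[iu[1]]
    d = dist[iu][mask]
    if d.size == 0:
        return 0.0
    s = 0.5 * (sig[iu[0]] + sig[iu[1]])[mask]
    e = np.sqrt(eps[iu[0]] * eps[iu[1]])[mask]
    qq = (q[iu[0]] * q[iu[1]])[mask]
    sr6 = (s / d) ** 6
    lj = 4.0 * e * (sr6 ** 2 - sr6)
    coul = COULOMB_KE * qq / (DIELECTRIC_SLOPE * d * d)
    return float(lj.sum() + coul.sum())


def _sasa_energy(atoms: Sequence[Atom], frame: Frame) -> float:
    """Solvation as surface tension times solvent-accessible area.

    The area comes from biotite's Shrake-Rupley implementation with the
    per-element radii above; an isolated atom yields exactly
    4 pi (r + probe)^2 times the coefficient.
    """
    atoms = list(atoms)
    if not atoms:
        return 0.0
    n = len(atoms)
    array = struc.AtomArray(n)
    array.coord = np.array([frame.coords[a.index] for a in atoms]).reshape(n, 3)
    array.chain_id = np.array(["A"] * n, dtype="U4")
    array.res_id = np.array([a.residue.number for a in atoms], dtype=int)
    array.res_name = np.array([a.residue.name for a in atoms], dtype="U5")
    array.atom_name = np.array([a.name for a in atoms], dtype="U6")
    array.element = np.array([a.element.upper() for a in atoms], dtype="U2")
    radii = np.array([VDW_RADII.get(a.element.upper(), 1.70) for a in atoms])
    area = struc.sasa(array, probe_radius=SASA_PROBE_RADIUS,
                      vdw_radii=radii, point_number=960)
    return float(SASA_COEFFICIENT * np.nansum(area))


def reference_backend(lj_params: dict | None = None) -> EnergyBackend:
    """The shipped desk-scale backend; see the module docstring."""
    params = dict(LJ_PARAMS)
    if lj_params:
        params.update({k.upper(): v for k, v in lj_params.items()})
    return EnergyBackend(
        potential_energy=lambda atoms, frame: _pair_potential(atoms, frame, params),
        solvation_energy=_sasa_energy,
        name="reference",
    )


# --- per-frame decomposition and traces ------------------------------------

def compute_components(system: MolecularSystem, frame: Frame,
                       backend: EnergyBackend) -> EnergyComponents:
    """Evaluate the six decomposition terms for one frame.

    The backend sees the receptor alone, the ligand alone and the
    receptor∪ligand union; waters and ions influence the result only
    through whatever screening the backend itself encodes.
    """
    receptor = system.atoms_with_role("receptor")
    ligand = system.atoms_with_role("ligand")
    try:
        return EnergyComponents(
            E_pot1=backend.potential_energy(receptor, frame),
            E_pot2=backend.potential_energy(ligand, frame),
            E_sol1=backend.solvation_energy(receptor, frame),
            E_sol2=backend.solvation_energy(ligand, frame),
            E_pot_comp=backend.potential_energy(receptor + ligand, frame),
            E_sol_comp=backend.solvation_energy(receptor + ligand, frame),
        )
    except Exception as exc:
        raise RuntimeError(
            f"energy backend {backend.name!r} failed on frame {frame.index}: {exc}"
        ) from exc


@dataclass
class BindingEnergyTrace:
    """Per-frame binding-energy series with its analysis window."""

    times: np.ndarray       # ns (frame index when times are unknown)
    energies: np.ndarray    # kJ/mol
    label: str = ""
    window_fraction: float = 0.4  # leading fraction excluded by default

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.shape != self.energies.shape:
            raise ValueError("times and energies must have equal length")


def compute_trace(system: MolecularSystem, backend: EnergyBackend,
                  label: str = "") -> BindingEnergyTrace:
    """Binding-energy series over all frames of a system."""
    energies = []
    times = []
    for fr in system.frames:
        energies.append(binding_energy(compute_components(system, fr, backend)))
        times.append(fr.time if fr.time is not None else float(fr.index))
    return BindingEnergyTrace(np.array(times), np.array(energies), label=label)


def trace_statistics(trace: BindingEnergyTrace,
                     window: float | tuple[float, float] | None = None
                     ) -> tuple[float, float]:
    """Mean and population SD of E_bind inside the analysis window.

    ``window`` is either an excluded leading fraction (default: the
    trace's ``window_fraction``, 0.4 — the equilibration portion) or
    explicit (t_start, t_end) time bounds.  The window is closed on
    both sides: a frame at exactly the boundary time is included.
    """
    if window is None:
        window = trace.window_fraction
    t = trace.times
    if np.isscalar(window):
        frac = float(window)
        if not (0.0 <= frac < 1.0):
            raise ValueError("window fraction must lie in [0, 1)")
        t0, t1 = t.min(), t.max()
        start = t0 + frac * (t1 - t0)
        mask = t >= start
    else:
        start, end = window
        mask = (t >= start) & (t <= end)
    if not mask.any():
        raise ValueError("analysis window contains no frames")
    vals = trace.energies[mask]
    return float(vals.mean()), float(vals.std())
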