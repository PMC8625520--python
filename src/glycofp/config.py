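"""YAML configuration for thresholds and typing tables.

All defaults live in code (:class:`glycofp.chemtype.TypingTables` and
the shipped oxygen-class map); a config file overrides selected keys:

.. code-block:: yaml

    hbond_energy_threshold: 6.25     # kJ/mol, strict ">"
    water_bridge_threshold: 3.0      # Å
    ionic_range: [0.0, 1.5]          # Å, adjusted distance
    hydrophobic_cutoff: 4.5          # Å
    his_protonated: false
    hbond_radii: {N: 1.75, O: 1.70, CA: 1.10}
    bridge_species: [CA, MG]
    role_rules: {XYL: ligand}
    oxygen_classes:                  # (residue, atom) -> class
      GCU:
        O2: O2
"""

from __future__ import annotations

import yaml

from .chemtype import TypingTables

__all__ = ["load_config", "AnalysisConfig"]


class AnalysisConfig:
    """Typed bundle of everything a pipeline run needs."""

    def __init__(self, tables: TypingTables | None = None,
                 bridge_species=("CA", "MG"),
                 role_rules: dict[str, str] | None = None,
                 oxygen_classes: dict[tuple[str, str], str] | None = None,
                 window_fraction: float = 0.4):
        self.tables = tables or TypingTables()
        self.bridge_species = tuple(bridge_species)
        self.role_rules = role_rules or {}
        self.oxygen_classes = oxygen_classes or {}
        self.window_fraction = window_fraction

    def echo(self) -> dict:
        """Config as a plain dict (for run logs)."""
        return {
            "hbond_energy_threshold": self.tables.hbond_energy_threshold,
            "water_bridge_threshold": self.tables.water_bridge_threshold,
            "ionic_range": list(self.tables.ionic_range),
            "hydrophobic_cutoff": self.tables.hydrophobic_cutoff,
            "his_protonated": self.tables.his_protonated,
            "hbond_radii": dict(self.tables.hbond_radii),
            "bridge_species": list(self.bridge_species),
            "window_fraction": self.window_fraction,
        }


def load_config(path: str | None) -> AnalysisConfig:
    """Read a YAML config file; ``None`` yields all defaults."""
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    tables = cfg.tables
    for key in ("hbond_energy_threshold", "water_bridge_threshold",
                "hydrophobic_cutoff", "his_protonated"):
        if key in data:
            setattr(tables, key, data[key])
    if "ionic_range" in data:
        lo, hi = data["ionic_range"]
        tables.ionic_range = (float(lo), float(hi))
    if "hbond_radii" in data:
        tables.hbond_radii.update(
            {str(k).upper(): float(v) for k, v in data["hbond_radii"].items()})
    if "bridge_species" in data:
        cfg.bridge_species = tuple(str(s).upper() for s in data["bridge_species"])
    if "role_rules" in data:
        cfg.role_rules = {str(k): str(v) for k, v in data["role_rules"].items()}
    if "oxygen_classes" in data:
        cfg.oxygen_classes = {
            (str(res).upper(), str(atom)): str(label)
            for res, atoms in data["oxygen_classes"].items()
            for atom, label in atoms.items()}
    if "window_fraction" in data:
        cfg.window_fraction = float(data["window_fraction"])
    return cfg
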