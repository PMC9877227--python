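"""Lipid species configuration: residue-name mapping, marker atoms, hydrophobicity
classes and formal headgroup charges.

A :class:`SpeciesConfig` describes one lipid species as the analyses see it: the
set of residue names that belong to it, the single headgroup *marker* atom that
represents the lipid's lateral position (the phosphorus atom for phospholipids,
the hydroxyl oxygen O3 for cholesterol), the split of its heavy atoms into
hydrophilic (headgroup) and hydrophobic (acyl-chain) classes, the formal charge
carried by the headgroup, and its mole fraction in the bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SpeciesConfig",
    "SpeciesRegistry",
    "load_species_config",
    "plasma_membrane_registry",
]

_MOLFRAC_TOL = 1e-9


@dataclass(frozen=True)
class SpeciesConfig:
    """One lipid species as seen by the analyses.

    Parameters
    ----------
    name
        Species label used in all outputs (e.g. ``"DOPC"``, ``"CHOL"``).
    resnames
        Residue names in the topology that belong to this species.
    marker
        Name of the single headgroup marker atom (P for phospholipids,
        O3 for sterols).
    hydrophilic, hydrophobic
        Disjoint sets of heavy-atom names forming the headgroup and tail
        classes used by the packing-defect classifier. The marker atom is
        conventionally part of the hydrophilic set.
    charge
        Formal headgroup charge in elementary charge units.
    molfrac
        Mole fraction of the species in the bilayer, in [0, 1].
    donors
        Optional mapping of donor heavy-atom name -> bonded hydrogen name,
        for lipids that can donate hydrogen bonds.
    """

    name: str
    resnames: frozenset[str]
    marker: str
    hydrophilic: frozenset[str]
    hydrophobic: frozenset[str]
    charge: int = 0
    molfrac: float = 0.0
    donors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hydrophilic & self.hydrophobic:
            raise ValueError(
                f"species {self.name!r}: hydrophilic and hydrophobic atom sets "
                f"overlap: {sorted(self.hydrophilic & self.hydrophobic)}"
            )
        if not self.marker:
            raise ValueError(f"species {self.name!r}: marker atom name is empty")
        if not 0.0 <= self.molfrac <= 1.0:
            raise ValueError(
                f"species {self.name!r}: mole fraction {self.molfrac} not in [0, 1]"
            )

    def atom_class(self, atom_name: str) -> str:
        """Return ``"hydrophilic"`` or ``"hydrophobic"`` for a heavy-atom name."""
        if atom_name in self.hydrophilic:
            return "hydrophilic"
        if atom_name in self.hydrophobic:
            return "hydrophobic"
        raise KeyError(
            f"atom {atom_name!r} has no hydrophobicity class in species {self.name!r}"
        )


class SpeciesRegistry:
    """Ordered collection of :class:`SpeciesConfig` with resname lookup."""

    def __init__(self, species: Iterable[SpeciesConfig], *, check_molfrac: bool = True):
        self.species: tuple[SpeciesConfig, ...] = tuple(species)
        if not self.species:
            raise ValueError("species registry is empty")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species names: {names}")
        self._by_resname: dict[str, SpeciesConfig] = {}
        for sp in self.species:
            for rn in sp.resnames:
                if rn in self._by_resname:
                    raise ValueError(
                        f"residue name {rn!r} claimed by both "
                        f"{self._by_resname[rn].name!r} and {sp.name!r}"
                    )
                self._by_resname[rn] = sp
        if check_molfrac:
            total = sum(s.molfrac for s in self.species)
            if abs(total - 1.0) > _MOLFRAC_TOL:
                raise ValueError(f"mole fractions sum to {total!r}, expected 1")

    def __iter__(self):
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def get(self, name: str) -> SpeciesConfig:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown species {name!r}")

    def for_resname(self, resname: str) -> SpeciesConfig | None:
        return self._by_resname.get(resname)

    @property
    def molfracs(self) -> dict[str, float]:
        return {s.name: s.molfrac for s in self.species}


def load_species_config(path: str | Path) -> SpeciesRegistry:
    """Load a species registry from a YAML file.

    Expected layout::

        species:
          - name: DOPC
            resnames: [DOPC]
            marker: P
            hydrophilic: [P, OH1, OH2]
            hydrophobic: [C1, C2, C3, C4]
            charge: 0
            molfrac: 0.40
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"species config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "species" not in raw:
        raise ValueError(f"{path}: expected a top-level 'species' list")
    entries = []
    for item in raw["species"]:
        entries.append(
            SpeciesConfig(
                name=str(item["name"]),
                resnames=frozenset(str(r) for r in item["resnames"]),
                marker=str(item["marker"]),
                hydrophilic=frozenset(str(a) for a in item.get("hydrophilic", [])),
                hydrophobic=frozenset(str(a) for a in item.get("hydrophobic", [])),
                charge=int(item.get("charge", 0)),
                molfrac=float(item.get("molfrac", 0.0)),
                donors=dict(item.get("donors", {})),
            )
        )
    return SpeciesRegistry(entries)


def save_species_config(registry: SpeciesRegistry, path: str | Path) -> None:
    """Write a registry back to the YAML layout read by :func:`load_species_config`."""
    payload = {
        "species": [
            {
                "name": s.name,
                "resnames": sorted(s.resnames),
                "marker": s.marker,
                "hydrophilic": sorted(s.hydrophilic),
                "hydrophobic": sorted(s.hydrophobic),
                "charge": s.charge,
                "molfrac": s.molfrac,
                **({"donors": dict(s.donors)} if s.donors else {}),
            }
            for s in registry
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# Coarse bead-model atom names used by the synthetic bilayer generator.
# Phospholipids: P marker + two headgroup oxygens above it, four tail carbons.
# Cholesterol: O3 hydroxyl marker + three ring/tail carbons.
PHOSPHOLIPID_HEAD = ("P", "OH1", "OH2")
PHOSPHOLIPID_TAIL = ("C1", "C2", "C3", "C4")
STEROL_HEAD = ("O3",)
STEROL_TAIL = ("C1", "C2", "C3")


def plasma_membrane_registry() -> SpeciesRegistry:
    """The five-species plasma-membrane model at 40:32:20:4:4 mol%.

    DOPC : cholesterol : DOPE : PIP : PIP2, with formal headgroup charges
    0 / 0 / 0 / -3 / -5 e placed at the marker atom.
    """

    def _phospho(name: str, charge: int, frac: float) -> SpeciesConfig:
        return SpeciesConfig(
            name=name,
            resnames=frozenset({name}),
            marker="P",
            hydrophilic=frozenset(PHOSPHOLIPID_HEAD),
            hydrophobic=frozenset(PHOSPHOLIPID_TAIL),
            charge=charge,
            molfrac=frac,
        )

    chol = SpeciesConfig(
        name="CHOL",
        resnames=frozenset({"CHOL", "CHL1"}),
        marker="O3",
        hydrophilic=frozenset(STEROL_HEAD),
        hydrophobic=frozenset(STEROL_TAIL),
        charge=0,
        molfrac=0.32,
    )
    return SpeciesRegistry(
        [
            _phospho("DOPC", 0, 0.40),
            chol,
            _phospho("DOPE", 0, 0.20),
            _phospho("PIP", -3, 0.04),
            _phospho("PIP2", -5, 0.04),
        ]
    )
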