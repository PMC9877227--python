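"""Shared fixtures: tiny hand-built systems and session-scoped synthetic runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lipidprint.species import SpeciesConfig, SpeciesRegistry
from lipidprint.system import MembraneSystem
from lipidprint.synth import SyntheticConfig, build_bilayer, generate


def make_system(rows, coords, box=(60.0, 60.0, 60.0), registry=None, domains=None,
                times=None):
    """Build a MembraneSystem from (name, resname, resid, segment, element)
    tuples and a (frames, atoms, 3) coordinate array."""
    atoms = pd.DataFrame(rows, columns=["name", "resname", "resid", "segment",
                                        "element"])
    atoms["resid"] = atoms.resid.astype(np.int64)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    nf = coords.shape[0]
    if registry is None:
        registry = simple_registry()
    return MembraneSystem(
        atoms=atoms, coords=coords,
        boxes=np.tile(np.asarray(box, float), (nf, 1)),
        times=np.arange(nf, dtype=float) if times is None else np.asarray(times),
        registry=registry,
        domains=domains if domains is not None else {"4HB": (1, 500)},
    )


def simple_registry(**fracs):
    """Small registry over the coarse bead names; default DOPC/PIP2 at 50:50."""
    if not fracs:
        fracs = {"DOPC": 0.5, "PIP2": 0.5}
    out = []
    for name, frac in fracs.items():
        charge = {"DOPC": 0, "DOPE": 0, "CHOL": 0, "PIP": -3, "PIP2": -5}.get(name, 0)
        out.append(SpeciesConfig(
            name=name, resnames=frozenset({name}), marker="P",
            hydrophilic=frozenset({"P", "OH1", "OH2"}),
            hydrophobic=frozenset({"C1", "C2", "C3", "C4"}),
            charge=charge, molfrac=frac))
    return SpeciesRegistry(out)


def lipid_rows(resname, resid, names=("P",)):
    return [(n, resname, resid, "lipid", "P" if n == "P" else
             ("O" if n.startswith("O") else "C")) for n in names]


def protein_residue_rows(resid, names=("CA",)):
    elem = {"CA": "C", "ND": "N", "HD": "H", "OA": "O"}
    return [(n, "ALA", resid, "protein", elem.get(n, "C")) for n in names]


@pytest.fixture(scope="session")
def small_build():
    """Single-frame 64-lipid-per-leaflet bilayer with bound-height protein."""
    return build_bilayer(SyntheticConfig.test_scale(n_frames=1, seed=11))


@pytest.fixture(scope="session")
def recruitment_run():
    """Short recruitment trajectory with PIP2 biased toward the protein."""
    cfg = SyntheticConfig.test_scale(
        n_frames=200, binding_frame=20, seed=7,
        recruitment_bias={"PIP2": 1.0},
    )
    system, truth = generate(cfg)
    return cfg, system, truth
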