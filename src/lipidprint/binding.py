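"""Protein-side binding observables.

Domain COM-membrane distances, per-residue contact frequency, per-domain x
per-species contact counts, insertion depth with the deepest inserted
residue, and Cα RMSD/RMSF after rigid-body superposition.

Contacts follow two distinct definitions, both kept as stated: per-residue
contact uses the residue Cα within 12 Å of binding-leaflet marker atoms,
while domain x species counts use *all* protein heavy atoms against the
markers of each species. Comparisons use a closed interval (distance <=
cutoff). Standard errors come from contiguous block averages (5 blocks by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import block_standard_error, DEFAULT_BLOCKS
from .system import MembraneSystem, pair_distances, CONTACT_CUTOFF

__all__ = [
    "ContactTable",
    "DepthProfile",
    "domain_com_distance",
    "residue_contact_frequency",
    "domain_species_contacts",
    "insertion_depth",
    "rmsd_series",
    "rmsf",
]


@dataclass
class ContactTable:
    """Contact statistics over a frame window."""

    per_residue: pd.DataFrame | None  # resid, domain, pct_time, se
    per_domain_species: pd.DataFrame | None  # domain, species, mean_count, se
    window: tuple[int, int]
    cutoff: float


@dataclass
class DepthProfile:
    """Signed per-residue insertion depth (positive = past the marker plane)."""

    depths: pd.Series  # resid -> mean depth, Å
    deepest_resid: int
    window: tuple[int, int]


def _window(system: MembraneSystem, window) -> tuple[int, int]:
    frames = system.frame_range(window)
    return frames.start, frames.stop


def _leaflet_marker_indices(system: MembraneSystem, frame: int, leaflet: str) -> np.ndarray:
    """Marker atom indices of one leaflet at one frame (midplane rule)."""
    markers = system.marker_index_by_resid.to_numpy()
    z = system.coords[frame, markers, 2]
    mid = z.mean()
    mask = z >= mid if leaflet == "upper" else z < mid
    return markers[mask]


def domain_com_distance(
    system: MembraneSystem,
    domain: str,
    window: tuple[int, int] | None = None,
    leaflet: str = "upper",
) -> np.ndarray:
    """|z of the domain's Cα center of mass - mean marker z of the binding
    leaflet| per frame, in Å."""
    if domain not in system.domains:
        raise KeyError(f"unknown domain {domain!r}; have {list(system.domains)}")
    lo, hi = system.domains[domain]
    ca = system.protein_ca_indices
    resids = system.atoms.resid.to_numpy()[ca]
    sel = ca[(resids >= lo) & (resids <= hi)]
    if len(sel) == 0:
        raise ValueError(f"domain {domain!r} has no Cα atoms")
    start, stop = _window(system, window)
    out = np.empty(stop - start)
    for i, f in enumerate(range(start, stop)):
        plane = system.coords[f, _leaflet_marker_indices(system, f, leaflet), 2].mean()
        out[i] = abs(system.coords[f, sel, 2].mean() - plane)
    return out


def _ca_marker_min_dist(system, frame, ca, leaflet):
    m = _leaflet_marker_indices(system, frame, leaflet)
    D = pair_distances(system.coords[frame, ca], system.coords[frame, m],
                       system.boxes[frame])
    return D.min(axis=1) if D.size else np.full(len(ca), np.inf)


def residue_contact_frequency(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    cutoff: float = CONTACT_CUTOFF,
    leaflet: str = "upper",
    n_blocks: int = DEFAULT_BLOCKS,
) -> ContactTable:
    """Percent of window frames each residue's Cα spends within ``cutoff`` of
    binding-leaflet marker atoms."""
    start, stop = _window(system, window)
    ca = system.protein_ca_indices
    if len(ca) == 0:
        raise ValueError("no protein present")
    resids = system.atoms.resid.to_numpy()[ca]
    hits = np.empty((stop - start, len(ca)), dtype=float)
    for i, f in enumerate(range(start, stop)):
        hits[i] = _ca_marker_min_dist(system, f, ca, leaflet) <= cutoff
    pct = 100.0 * hits.mean(axis=0)
    se = np.array([100.0 * block_standard_error(hits[:, j], n_blocks)
                   for j in range(len(ca))])
    table = pd.DataFrame(
        {"resid": resids,
         "domain": [system.domain_of(int(r)) for r in resids],
         "pct_time": pct, "se": se}
    ).sort_values("resid", ignore_index=True)
    return ContactTable(per_residue=table, per_domain_species=None,
                        window=(start, stop), cutoff=cutoff)


def domain_species_contacts(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    cutoff: float = CONTACT_CUTOFF,
    leaflet: str = "upper",
    n_blocks: int = DEFAULT_BLOCKS,
) -> ContactTable:
    """Mean per-frame count of (protein heavy atom, species marker) pairs
    within ``cutoff``, summed per protein domain."""
    start, stop = _window(system, window)
    heavy = system.protein_heavy_indices
    if len(heavy) == 0:
        raise ValueError("no protein present")
    resids = system.atoms.resid.to_numpy()[heavy]
    domains = np.array([system.domain_of(int(r)) for r in resids])
    domain_labels = [d for d in list(system.domains) if (domains == d).any()]
    species_names = system.registry.names

    sp_by_resid = system.lipid_species_by_resid
    counts = {(d, s): np.zeros(stop - start) for d in domain_labels for s in species_names}
    for i, f in enumerate(range(start, stop)):
        m = _leaflet_marker_indices(system, f, leaflet)
        if len(m) == 0:
            continue
        m_res = system.atoms.resid.to_numpy()[m]
        m_sp = sp_by_resid.loc[m_res].to_numpy()
        D = pair_distances(system.coords[f, heavy], system.coords[f, m],
                           system.boxes[f])
        hit = D <= cutoff
        for d in domain_labels:
            row = hit[domains == d]
            for s in species_names:
                counts[(d, s)][i] = row[:, m_sp == s].sum()
    rows = [
        {"domain": d, "species": s,
         "mean_count": counts[(d, s)].mean(),
         "se": block_standard_error(counts[(d, s)], n_blocks)}
        for d in domain_labels for s in species_names
    ]
    return ContactTable(per_residue=None, per_domain_species=pd.DataFrame(rows),
                        window=(start, stop), cutoff=cutoff)


def insertion_depth(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    leaflet: str = "upper",
    cutoff: float = CONTACT_CUTOFF,
) -> DepthProfile:
    """Mean signed depth of each contacting residue past the marker plane.

    Positive depth means the Cα sits past the binding-leaflet marker plane
    toward the bilayer core. Only residues whose Cα is ever within ``cutoff``
    of a binding-leaflet marker during the window are profiled. The deepest
    residue maximizes mean depth (ties break to the lowest residue id).
    """
    start, stop = _window(system, window)
    ca = system.protein_ca_indices
    resids = system.atoms.resid.to_numpy()[ca]
    sign = 1.0 if leaflet == "upper" else -1.0
    depth = np.zeros((stop - start, len(ca)))
    ever = np.zeros(len(ca), dtype=bool)
    for i, f in enumerate(range(start, stop)):
        m = _leaflet_marker_indices(system, f, leaflet)
        plane = system.coords[f, m, 2].mean()
        depth[i] = sign * (plane - system.coords[f, ca, 2])
        ever |= _ca_marker_min_dist(system, f, ca, leaflet) <= cutoff
    if not ever.any():
        raise ValueError("no residue ever within the contact cutoff")
    mean_depth = depth.mean(axis=0)
    profile = pd.Series(mean_depth[ever], index=resids[ever].astype(int)).sort_index()
    best = profile.max()
    deepest = int(profile.index[np.isclose(profile.to_numpy(), best)].min())
    return DepthProfile(depths=profile, deepest_resid=deepest, window=(start, stop))


# -- RMSD / RMSF -----------------------------------------------------------


def _kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Least-squares superpose P onto Q (rotation + translation); returns
    the transformed copy of P."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return Pc @ R.T + Q.mean(axis=0)


def _ca_selection(system: MembraneSystem, domain: str | None) -> np.ndarray:
    ca = system.protein_ca_indices
    if domain is None:
        sel = ca
    else:
        if domain not in system.domains:
            raise KeyError(f"unknown domain {domain!r}")
        lo, hi = system.domains[domain]
        resids = system.atoms.resid.to_numpy()[ca]
        sel = ca[(resids >= lo) & (resids <= hi)]
    if len(sel) == 0:
        raise ValueError("empty Cα selection")
    return sel


def rmsd_series(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    reference_frame: int = 0,
    domain: str | None = None,
) -> np.ndarray:
    """Cα RMSD vs a reference frame after rigid-body superposition, per frame."""
    sel = _ca_selection(system, domain)
    start, stop = _window(system, window)
    ref = system.coords[reference_frame, sel]
    out = np.empty(stop - start)
    for i, f in enumerate(range(start, stop)):
        moved = _kabsch_superpose(system.coords[f, sel], ref)
        out[i] = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    return out


def rmsf(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    domain: str | None = None,
) -> pd.Series:
    """Per-residue Cα RMSF about the window-mean structure after superposition."""
    sel = _ca_selection(system, domain)
    start, stop = _window(system, window)
    ref = system.coords[start, sel]
    aligned = np.stack([_kabsch_superpose(system.coords[f, sel], ref)
                        for f in range(start, stop)])
    mean_struct = aligned.mean(axis=0)
    aligned = np.stack([_kabsch_superpose(X, mean_struct) for X in aligned])
    mean_struct = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean_struct) ** 2, axis=2), axis=0))
    resids = system.atoms.resid.to_numpy()[sel].astype(int)
    return pd.Series(fluct, index=resids).sort_index()
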