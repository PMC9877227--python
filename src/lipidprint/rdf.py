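"""Radial distribution functions for protein-lipid and lipid-lipid pairs.

The estimator is the standard pair-distance histogram with minimum-image
distances, normalized per frame by the spherical shell volume 4 pi r² dr and
the target number density in the box, then averaged over the window. For the
leaflet-restricted lipid-lipid case a 2D (lateral) variant normalizing by the
annulus area 2 pi r dr and the leaflet surface density is available behind a
flag; the 3D convention is the default. The reference for protein-anchored
RDFs is typically the Cα of the deepest inserted residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import MembraneSystem, pair_distances

__all__ = ["RDFResult", "rdf", "lipid_lipid_rdf"]


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, Å
    g: np.ndarray
    dr: float
    r_max: float
    reference: str
    target: str
    frames_used: int


def _check_rmax(system: MembraneSystem, r_max: float, frames) -> None:
    half_min = min(system.boxes[list(frames)].min(axis=0)) / 2.0
    if r_max > half_min + 1e-9:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box length ({half_min:.2f})"
        )


def _accumulate(system, ref_idx_per_frame, tgt_idx_per_frame, frames, dr, r_max,
                lateral: bool, exclude_same_atom: bool, exclude_same_resid: bool):
    nbins = int(np.ceil(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    hist = np.zeros(nbins)
    norm = 0.0
    resid = system.atoms.resid.to_numpy()
    for f in frames:
        ref = ref_idx_per_frame(f)
        tgt = tgt_idx_per_frame(f)
        if len(ref) == 0 or len(tgt) == 0:
            raise ValueError("empty selection")
        box = system.boxes[f]
        if lateral:
            a = system.coords[f, ref][:, :2]
            b = system.coords[f, tgt][:, :2]
            D = pair_distances(
                np.column_stack([a, np.zeros(len(a))]),
                np.column_stack([b, np.zeros(len(b))]),
                np.array([box[0], box[1], 1.0]),
            )
        else:
            D = pair_distances(system.coords[f, ref], system.coords[f, tgt], box)
        keep = np.ones_like(D, dtype=bool)
        if exclude_same_atom:
            keep &= ref[:, None] != tgt[None, :]
        if exclude_same_resid:
            keep &= resid[ref][:, None] != resid[tgt][None, :]
        d = D[keep & (D < r_max)]
        hist += np.histogram(d, bins=edges)[0]
        if lateral:
            density = len(tgt) / (box[0] * box[1])
        else:
            density = len(tgt) / np.prod(box)
        norm += len(ref) * density
    r_mid = (edges[:-1] + edges[1:]) / 2.0
    if lateral:
        shell = 2.0 * np.pi * r_mid * dr
    else:
        shell = 4.0 * np.pi * r_mid**2 * dr
    g = hist / (norm * shell)
    return r_mid, g


def rdf(
    system: MembraneSystem,
    reference: np.ndarray | int,
    target_species: str,
    window: tuple[int, int] | None = None,
    dr: float = 0.1,
    r_max: float | None = None,
) -> RDFResult:
    """g(r) from fixed reference atoms to the marker atoms of one species.

    ``reference`` is an array of atom indices or a single protein residue id
    whose Cα is used (the deepest-inserted-residue convention).
    """
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    if isinstance(reference, (int, np.integer)):
        ref_idx = np.array([system.ca_index_of_residue(int(reference))])
        ref_desc = f"Cα of residue {int(reference)}"
    else:
        ref_idx = np.asarray(reference, dtype=np.int64)
        ref_desc = f"{len(ref_idx)} reference atoms"
    if len(ref_idx) == 0:
        raise ValueError("empty selection")
    tgt = system.marker_indices(target_species)
    if len(tgt) == 0:
        raise ValueError("empty selection")
    if r_max is None:
        r_max = float(min(system.boxes[frames.start]) / 2.0)
    _check_rmax(system, r_max, frames)
    r, g = _accumulate(system, lambda f: ref_idx, lambda f: tgt, frames, dr,
                       r_max, lateral=False, exclude_same_atom=True,
                       exclude_same_resid=False)
    return RDFResult(r=r, g=g, dr=dr, r_max=r_max, reference=ref_desc,
                     target=target_species, frames_used=len(frames))


def lipid_lipid_rdf(
    system: MembraneSystem,
    species_a: str,
    species_b: str,
    leaflet: str = "upper",
    window: tuple[int, int] | None = None,
    dr: float = 0.1,
    r_max: float | None = None,
    lateral: bool = False,
) -> RDFResult:
    """g(r) between marker atoms of two species within one leaflet.

    Self-pairs are excluded when ``species_a == species_b``. ``lateral=True``
    switches to in-plane (2D) distances and annulus normalization.
    """
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    markers = system.marker_index_by_resid
    sp = system.lipid_species_by_resid

    def leaflet_markers(f, species):
        idx = markers.to_numpy()
        z = system.coords[f, idx, 2]
        mid = z.mean()
        in_leaf = z >= mid if leaflet == "upper" else z < mid
        resids = markers.index.to_numpy()[in_leaf]
        resids = resids[sp.loc[resids].to_numpy() == species]
        return markers.loc[resids].to_numpy()

    if r_max is None:
        r_max = float(min(system.boxes[frames.start]) / 2.0)
    _check_rmax(system, r_max, frames)
    same = species_a == species_b
    r, g = _accumulate(
        system,
        lambda f: leaflet_markers(f, species_a),
        lambda f: leaflet_markers(f, species_b),
        frames, dr, r_max, lateral=lateral,
        exclude_same_atom=True, exclude_same_resid=same,
    )
    return RDFResult(r=r, g=g, dr=dr, r_max=r_max,
                     reference=f"{species_a} markers ({leaflet})",
                     target=species_b, frames_used=len(frames))
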