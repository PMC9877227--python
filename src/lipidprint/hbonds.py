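"""Geometric hydrogen-bond detection between protein and lipids.

The criterion is the standard geometric one: donor-acceptor heavy-atom
distance <= 3.2 Å and a D-H...A angle within 30° of linearity (i.e. the
angle at the hydrogen >= 150°). Donors are N/O atoms with a bonded hydrogen
(covalent distance < 1.2 Å for the protein; name-pairing from the species
configuration for lipids), acceptors are all N/O atoms. Pairs within the
same residue are excluded. Detection is per frame with no occupancy
smoothing; counts are reported as (D, H, A) triples, with unique (D, A)
pairs available as well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blocks import block_standard_error, DEFAULT_BLOCKS
from .system import MembraneSystem, minimum_image_displacement

__all__ = [
    "find_donors_acceptors",
    "detect_hbonds",
    "count_hbonds_by_species",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
]

HBOND_DISTANCE_CUTOFF = 3.2  # Å, donor-acceptor heavy-atom distance
HBOND_ANGLE_CUTOFF = 30.0  # degrees of allowed deviation from linearity
_COVALENT_DH = 1.2  # Å, donor-hydrogen bond detection for the protein


def find_donors_acceptors(
    system: MembraneSystem, frame: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate donor (D, H) atom-index pairs and acceptor atom indices.

    Protein donors pair each hydrogen with the nearest N/O within 1.2 Å at
    the given frame; a hydrogen with no resolvable parent raises. Lipid
    donors come from each species' configured donor->hydrogen name map.
    Acceptors are every protein or lipid N/O atom.
    """
    atoms = system.atoms
    is_prot = atoms.segment == "protein"
    is_lip = atoms.segment == "lipid"
    is_no = atoms.element.isin(["N", "O"])

    donors: list[tuple[int, int]] = []
    # protein: covalent-distance pairing
    h_idx = atoms.index[is_prot & (atoms.element == "H")].to_numpy()
    no_idx = atoms.index[is_prot & is_no].to_numpy()
    if len(h_idx) and len(no_idx):
        hp = system.coords[frame, h_idx]
        np_ = system.coords[frame, no_idx]
        d = minimum_image_displacement(hp[:, None, :], np_[None, :, :],
                                       system.boxes[frame])
        dist = np.sqrt((d ** 2).sum(-1))
        for i, h in enumerate(h_idx):
            j = int(np.argmin(dist[i]))
            if dist[i, j] >= _COVALENT_DH:
                raise ValueError(
                    f"hydrogen atom {int(h)} has no parent N/O within "
                    f"{_COVALENT_DH} Å"
                )
            donors.append((int(no_idx[j]), int(h)))
    elif len(h_idx):
        raise ValueError("protein hydrogens present but no N/O parents")

    # lipids: name-pairing from the species config
    lip = atoms[is_lip]
    for resid, grp in lip.groupby("resid"):
        sp = system.registry.for_resname(grp.resname.iloc[0])
        for d_name, h_name in sp.donors.items():
            d_sel = grp.index[grp.name == d_name]
            h_sel = grp.index[grp.name == h_name]
            if len(d_sel) == 1 and len(h_sel) == 1:
                donors.append((int(d_sel[0]), int(h_sel[0])))

    acceptors = atoms.index[(is_prot | is_lip) & is_no].to_numpy()
    donors_arr = np.array(sorted(donors), dtype=np.int64).reshape(-1, 2)
    return donors_arr, acceptors


def detect_hbonds(
    system: MembraneSystem,
    frame: int,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    donors_acceptors: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Detect all hydrogen bonds in one frame.

    Returns a DataFrame with columns frame, donor, hydrogen, acceptor,
    distance (Å), angle (degrees, at the hydrogen), donor_side
    (protein|lipid) and acceptor_group (lipid species name, or the protein
    domain of the acceptor residue), ordered by (donor, acceptor).
    """
    if donors_acceptors is None:
        donors_acceptors = find_donors_acceptors(system, frame=0)
    donors, acceptors = donors_acceptors
    if len(donors) == 0 or len(acceptors) == 0:
        return _empty_records()

    box = system.boxes[frame]
    D = system.coords[frame, donors[:, 0]]
    H = system.coords[frame, donors[:, 1]]
    A = system.coords[frame, acceptors]
    dv = minimum_image_displacement(D[:, None, :], A[None, :, :], box)
    dist = np.sqrt((dv ** 2).sum(-1))
    resid = system.atoms.resid.to_numpy()
    same_res = resid[donors[:, 0]][:, None] == resid[acceptors][None, :]
    same_atom = donors[:, 0][:, None] == acceptors[None, :]
    cand = (dist <= d_cut) & ~same_res & ~same_atom

    seg = system.atoms.segment
    sp_by_resid = system.lipid_species_by_resid
    min_ang = 180.0 - angle_cut
    rows = []
    for i, j in zip(*np.where(cand)):
        h = H[i]
        v1 = minimum_image_displacement(h, D[i], box)
        v2 = minimum_image_displacement(h, A[j], box)
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang < min_ang:
            continue
        d_idx, a_idx = int(donors[i, 0]), int(acceptors[j])
        donor_side = seg[d_idx]
        if seg[a_idx] == "lipid":
            group = sp_by_resid.loc[int(resid[a_idx])]
        else:
            group = system.domain_of(int(resid[a_idx]))
        rows.append((frame, d_idx, int(donors[i, 1]), a_idx,
                     float(dist[i, j]), float(ang), donor_side, group))
    if not rows:
        return _empty_records()
    out = pd.DataFrame(rows, columns=["frame", "donor", "hydrogen", "acceptor",
                                      "distance", "angle", "donor_side",
                                      "acceptor_group"])
    return out.sort_values(["donor", "acceptor"], ignore_index=True)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["frame", "donor", "hydrogen", "acceptor", "distance",
                 "angle", "donor_side", "acceptor_group"]
    )


def count_hbonds_by_species(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    n_blocks: int = DEFAULT_BLOCKS,
) -> pd.DataFrame:
    """Per-frame protein-lipid hydrogen-bond counts aggregated per species.

    Returns one row per species with the window mean, total, block SE and the
    unique (donor, acceptor) pair mean. Only bonds with one side on the
    protein and the other on a lipid are counted.
    """
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    da = find_donors_acceptors(system, frame=0)
    species = system.registry.names
    counts = {s: np.zeros(len(frames)) for s in species}
    pair_counts = {s: np.zeros(len(frames)) for s in species}
    seg = system.atoms.segment
    sp_by_resid = system.lipid_species_by_resid
    resid = system.atoms.resid
    for i, f in enumerate(frames):
        rec = detect_hbonds(system, f, d_cut, angle_cut, donors_acceptors=da)
        if rec.empty:
            continue
        prot_lip = rec[
            ((rec.donor_side == "protein") & (rec.acceptor.map(seg) == "lipid"))
            | ((rec.donor_side == "lipid") & (rec.acceptor.map(seg) == "protein"))
        ]
        for _, row in prot_lip.iterrows():
            lip_atom = row.acceptor if seg[row.acceptor] == "lipid" else row.donor
            s = sp_by_resid.loc[int(resid[lip_atom])]
            counts[s][i] += 1
        uniq = prot_lip.drop_duplicates(["donor", "acceptor"])
        for _, row in uniq.iterrows():
            lip_atom = row.acceptor if seg[row.acceptor] == "lipid" else row.donor
            s = sp_by_resid.loc[int(resid[lip_atom])]
            pair_counts[s][i] += 1
    rows = [
        {"species": s, "mean": counts[s].mean(), "total": counts[s].sum(),
         "se": block_standard_error(counts[s], n_blocks),
         "unique_pair_mean": pair_counts[s].mean()}
        for s in species
    ]
    return pd.DataFrame(rows)
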