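"""Synthetic bilayer + pseudo-protein trajectory generator with known ground truth.

The generator emulates the study system the analyses were designed for: a
two-leaflet bilayer of five species (DOPC:Chol:DOPE:PIP:PIP2 at 40:32:20:4:4
mol%), ~17x17 nm laterally at full scale with 600 lipids per leaflet, lateral
Brownian diffusion of lipids, a rigid pseudo-protein that descends onto the
upper leaflet and stays bound, optional kinematic recruitment of chosen
species toward the protein axis, and plantable hydrogen-bond geometries and
hydrophobic-exposure patches for detector fixtures.

Lipids are coarse bead clusters, not molecules: a phospholipid is one P
marker bead plus two headgroup oxygens above it and four tail carbons below;
cholesterol is an O3 marker plus three tail carbons. Beads carry explicit
rasterization radii sized so that headgroup disks tile the leaflet surface at
the lattice spacing, which is what the packing-defect classifier consumes.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .species import (
    SpeciesRegistry,
    plasma_membrane_registry,
    save_species_config,
    PHOSPHOLIPID_HEAD,
    PHOSPHOLIPID_TAIL,
    STEROL_HEAD,
    STEROL_TAIL,
)
from .system import MembraneSystem, write_system, minimum_image_displacement

__all__ = [
    "SyntheticConfig",
    "build_bilayer",
    "simulate",
    "generate",
    "plant_hbond_geometry",
    "plant_defect_patch",
    "largest_remainder_counts",
    "write_outputs",
]

# bead geometry (Å): z offsets from the marker plane, toward water (+) / core (-)
_HEAD_DZ = (0.0, 1.4, 2.8)  # P, OH1, OH2
_TAIL_DZ = (-3.0, -6.0, -9.0, -12.0)  # C1..C4
_STEROL_TAIL_DZ = (-3.5, -7.0, -10.5)
_HEAD_RADIUS = 6.0  # rasterization radii of the coarse beads
_TAIL_RADIUS = 5.0
_PROTEIN_CA_RADIUS = 3.0

_ELEMENT = {"P": "P", "OH1": "O", "OH2": "O", "O3": "O",
            "CA": "C", "ND": "N", "HD": "H", "OA": "O"}

_LIPID_RESID_BASE = 1000  # lipid resids start above protein resids


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic bilayer trajectory.

    Defaults mirror the full-scale study system: 600 lipids per leaflet of
    DOPC:Chol:DOPE:PIP:PIP2 at 40:32:20:4:4 mol% in a 173 Å lateral box.
    ``test_scale`` gives a 64-lipid-per-leaflet system at the same areal
    density for fast tests.
    """

    lipids_per_leaflet: int = 600
    mole_fractions: dict[str, float] = field(
        default_factory=lambda: {"DOPC": 0.40, "CHOL": 0.32, "DOPE": 0.20,
                                 "PIP": 0.04, "PIP2": 0.04}
    )
    box_xy: float = 173.0  # Å
    box_z: float = 180.0  # Å
    jitter_frac: float = 0.15  # lattice jitter as fraction of spacing
    leaflet_offset: float = 19.0  # |z| of the marker planes, Å
    diffusion: float = 1.0  # lateral D, Å²/ns
    frame_interval: float = 1.0  # ns
    n_frames: int = 100
    z_jitter: float = 0.15  # per-frame σ of lipid z noise, Å
    protein_radius: float = 15.0  # Å
    protein_residues: int = 60
    start_height: float = 40.0  # Cα plane above marker plane at frame 0, Å
    bound_height: float = 6.0  # Cα plane above marker plane once bound, Å
    inserted_residue_depth: float = 2.0  # deepest residue Cα below plane, Å
    binding_frame: int = 50
    recruitment_bias: dict[str, float] = field(default_factory=dict)  # Å/ns
    capture_radius: float = 30.0  # Å
    min_radius: float = 2.0  # drift stops here to avoid pileup, Å
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mole_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {total}, expected 1")
        if self.lipids_per_leaflet < 0 or self.n_frames < 1:
            raise ValueError("counts must be non-negative, n_frames >= 1")
        if self.diffusion < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        pos = [f for f in self.mole_fractions.values() if f > 0]
        if pos and self.lipids_per_leaflet * min(pos) < 1:
            raise ValueError(
                "composition infeasible: smallest positive mole fraction yields "
                "less than one lipid per leaflet"
            )

    @classmethod
    def test_scale(cls, **overrides) -> "SyntheticConfig":
        """Small system at the same areal density (~49.9 Å² per lipid)."""
        defaults = dict(
            lipids_per_leaflet=64,
            box_xy=56.5,
            box_z=130.0,
            protein_radius=10.0,
            protein_residues=30,
            start_height=30.0,
            binding_frame=20,
            n_frames=100,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def registry(self) -> SpeciesRegistry:
        base = plasma_membrane_registry()
        out = []
        for sp in base:
            frac = self.mole_fractions.get(sp.name, 0.0)
            out.append(
                type(sp)(
                    name=sp.name, resnames=sp.resnames, marker=sp.marker,
                    hydrophilic=sp.hydrophilic, hydrophobic=sp.hydrophobic,
                    charge=sp.charge, molfrac=frac, donors=sp.donors,
                )
            )
        return SpeciesRegistry(out)


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer species counts summing to ``n`` by largest-remainder rounding."""
    raw = {k: n * f for k, f in fractions.items()}
    base = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), list(fractions).index(k)))
    for k in order[:short]:
        base[k] += 1
    return base


def _protein_layout(cfg: SyntheticConfig) -> np.ndarray:
    """Sunflower-disk xy offsets for the pseudo-protein residues (Å)."""
    n = cfg.protein_residues
    i = np.arange(n)
    r = cfg.protein_radius * np.sqrt((i + 0.5) / n)
    theta = i * (np.pi * (3.0 - np.sqrt(5.0)))
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def build_bilayer(config: SyntheticConfig) -> MembraneSystem:
    """Place lipids on a jittered square lattice per leaflet plus a rigid
    pseudo-protein above the upper leaflet; returns a single-frame system."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.lipids_per_leaflet
    counts = largest_remainder_counts(n, cfg.mole_fractions)
    registry = cfg.registry()

    # rectangular lattice covering the box with no unfilled sites: the last
    # row is stretched evenly when n does not fill the grid
    n_x = max(1, math.ceil(math.sqrt(n)))
    n_y = max(1, math.ceil(n / n_x))
    sx, sy = cfg.box_xy / n_x, cfg.box_xy / n_y
    spacing = min(sx, sy)
    site_list = []
    for j in range(n_y):
        in_row = n_x if j < n_y - 1 else n - n_x * (n_y - 1)
        row_sx = cfg.box_xy / max(in_row, 1)
        for i in range(in_row):
            site_list.append(((i + 0.5) * row_sx, (j + 0.5) * sy))
    sites = np.array(site_list)

    names, resnames, resids, segments, elements, radii = [], [], [], [], [], []
    positions = []
    resid = _LIPID_RESID_BASE

    for leaflet_sign, z_off in ((1, cfg.leaflet_offset), (-1, -cfg.leaflet_offset)):
        # interleave species over lattice sites, deterministically shuffled
        species_seq = [name for name, c in counts.items() for _ in range(c)]
        order = rng.permutation(len(species_seq))
        jitter = rng.uniform(-cfg.jitter_frac * spacing, cfg.jitter_frac * spacing,
                             size=(n, 2))
        xy = (sites + jitter) % cfg.box_xy
        for k in range(n):
            resid += 1
            sp_name = species_seq[order[k]]
            sp = registry.get(sp_name)
            sterol = sp.marker == "O3"
            head = STEROL_HEAD if sterol else PHOSPHOLIPID_HEAD
            tail = STEROL_TAIL if sterol else PHOSPHOLIPID_TAIL
            head_dz = _HEAD_DZ[: len(head)]
            tail_dz = _STEROL_TAIL_DZ if sterol else _TAIL_DZ
            rn = sorted(sp.resnames)[0]
            for nm, dz in zip(head, head_dz):
                names.append(nm)
                resnames.append(rn)
                resids.append(resid)
                segments.append("lipid")
                elements.append(_ELEMENT[nm] if nm in _ELEMENT else "O")
                radii.append(_HEAD_RADIUS)
                positions.append([xy[k, 0], xy[k, 1],
                                  z_off + (dz if leaflet_sign > 0 else -dz)])
            for nm, dz in zip(tail, tail_dz):
                names.append(nm)
                resnames.append(rn)
                resids.append(resid)
                segments.append("lipid")
                elements.append("C")
                radii.append(_TAIL_RADIUS)
                positions.append([xy[k, 0], xy[k, 1],
                                  z_off + (dz if leaflet_sign > 0 else -dz)])

    # rigid pseudo-protein above the upper leaflet
    center = cfg.box_xy / 2.0
    layout = _protein_layout(cfg)
    plane = cfg.leaflet_offset
    z_ca = plane + cfg.start_height
    for ridx in range(cfg.protein_residues):
        prot_resid = ridx + 1
        dx, dy = layout[ridx]
        # residue 1 (disk center) is the planted deepest residue: it hangs
        # below the Cα plane by bound_height + inserted_residue_depth
        hang = (cfg.bound_height + cfg.inserted_residue_depth) if ridx == 0 else 0.0
        ca = np.array([center + dx, center + dy, z_ca - hang])
        for nm, off, rad in (
            ("CA", (0.0, 0.0, 0.0), _PROTEIN_CA_RADIUS),
            ("ND", (0.6, 0.0, -0.8), 1.6),
            ("HD", (0.6, 0.0, -1.8), 1.2),
            ("OA", (-0.9, 0.0, -0.7), 1.6),
        ):
            names.append(nm)
            resnames.append("ALA")
            resids.append(prot_resid)
            segments.append("protein")
            elements.append(_ELEMENT[nm])
            radii.append(rad)
            positions.append(list(ca + np.asarray(off)))

    atoms = pd.DataFrame(
        {"name": names, "resname": resnames, "resid": np.asarray(resids, np.int64),
         "segment": segments, "element": elements, "radius": radii}
    )
    coords = np.asarray(positions, dtype=np.float64)[None, :, :]
    # center z coordinates inside [0, box_z)
    coords[..., 2] += cfg.box_z / 2.0
    boxes = np.array([[cfg.box_xy, cfg.box_xy, cfg.box_z]])
    nres = cfg.protein_residues
    domains = {
        "4HB": (1, max(1, nres // 3)),
        "brace": (max(1, nres // 3) + 1, max(2, 2 * nres // 3)),
        "PsK": (max(2, 2 * nres // 3) + 1, nres),
    }
    return MembraneSystem(atoms=atoms, coords=coords, boxes=boxes,
                          times=np.array([0.0]), registry=registry,
                          domains=domains)


def _lipid_groups(system: MembraneSystem):
    """(resids, list of atom-index arrays, marker indices) for all lipids."""
    lipid = system.atoms[system.atoms.segment == "lipid"]
    resids = np.sort(lipid.resid.unique())
    groups = [lipid.index[lipid.resid == r].to_numpy() for r in resids]
    markers = system.marker_index_by_resid.loc[resids].to_numpy()
    return resids, groups, markers


def simulate(initial: MembraneSystem, config: SyntheticConfig) -> MembraneSystem:
    """Propagate the single-frame system: 2D Brownian lipid diffusion with
    periodic wrapping, small z jitter, protein descent to the bound height at
    the binding frame, and post-binding kinematic recruitment of biased
    species toward the protein axis inside the capture radius."""
    cfg = config
    if initial.n_frames != 1:
        raise ValueError("initial system must have exactly one frame")
    rng = np.random.default_rng([cfg.seed, 1])
    box = initial.boxes[0]
    L = box[:2]
    dt = cfg.frame_interval
    sigma = math.sqrt(2.0 * cfg.diffusion * dt)

    resids, groups, markers = _lipid_groups(initial)
    n_lip = len(resids)
    species = initial.lipid_species_by_resid.loc[resids].to_numpy()
    prot_idx = initial.atoms.index[initial.atoms.segment == "protein"].to_numpy()
    center = np.array([cfg.box_xy / 2.0, cfg.box_xy / 2.0])
    # upper leaflet = markers above the box midplane in the build frame
    upper = initial.coords[0, markers, 2] >= cfg.box_z / 2.0

    base = initial.coords[0]
    lipid_xy = base[markers, :2].copy()  # marker positions drive whole-lipid moves
    prot_z0 = base[prot_idx, 2].copy()
    descent = cfg.start_height - cfg.bound_height

    bias = np.zeros(n_lip)
    for sp_name, b in cfg.recruitment_bias.items():
        bias[(species == sp_name) & upper] = b

    frames = np.empty((cfg.n_frames, initial.n_atoms, 3))
    frames[0] = base
    offsets = np.zeros((n_lip, 2))  # cumulative lateral displacement per lipid
    for f in range(1, cfg.n_frames):
        if cfg.diffusion > 0:
            offsets += rng.normal(0.0, sigma, size=(n_lip, 2))
        zj = rng.normal(0.0, cfg.z_jitter, size=n_lip) if cfg.z_jitter > 0 else np.zeros(n_lip)
        if f > cfg.binding_frame:
            cur = (lipid_xy + offsets)
            d = cur - center
            d -= L * np.round(d / L)
            r = np.hypot(d[:, 0], d[:, 1])
            move = (bias > 0) & (r > cfg.min_radius) & (r < cfg.capture_radius)
            if move.any():
                step = np.minimum(bias[move] * dt, r[move] - cfg.min_radius)
                offsets[move] -= d[move] / r[move, None] * step[:, None]

        frame = base.copy()
        for k in range(n_lip):
            idx = groups[k]
            frame[idx, 0] += offsets[k, 0]
            frame[idx, 1] += offsets[k, 1]
            frame[idx, 2] += zj[k]
        # wrap whole lipids by their marker position
        mk = frame[markers, :2]
        shift = -L * np.floor(mk / L)
        for k in range(n_lip):
            frame[groups[k], :2] += shift[k]

        if f < cfg.binding_frame:
            drop = descent * f / cfg.binding_frame
        else:
            drop = descent
        frame[prot_idx, 2] = prot_z0 - drop
        frames[f] = frame

    times = np.arange(cfg.n_frames) * dt
    boxes = np.repeat(initial.boxes, cfg.n_frames, axis=0)
    return MembraneSystem(atoms=initial.atoms.copy(), coords=frames, boxes=boxes,
                          times=times, registry=initial.registry,
                          domains=dict(initial.domains))


def generate(config: SyntheticConfig) -> tuple[MembraneSystem, dict]:
    """Build + simulate, returning the trajectory and its ground-truth tables."""
    cfg = config
    system = simulate(build_bilayer(cfg), cfg)
    resids, _, markers = _lipid_groups(system)
    upper = system.coords[0, markers, 2] >= cfg.box_z / 2.0
    species = system.lipid_species_by_resid.loc[resids]
    # first frame with any Cα within 12 Å of a marker, by direct scan
    ca = system.atoms.index[(system.atoms.segment == "protein")
                            & (system.atoms.name == "CA")].to_numpy()
    first_contact = None
    L = system.boxes[0]
    for f in range(system.n_frames):
        d = system.coords[f, ca][:, None, :] - system.coords[f, markers][None, :, :]
        d -= L * np.round(d / L)
        if (np.sqrt((d ** 2).sum(-1)) <= 12.0).any():
            first_contact = f
            break
    truth = {
        "first_contact_frame": first_contact,
        "config": asdict(cfg),
        "leaflet_by_resid": {int(r): ("upper" if u else "lower")
                             for r, u in zip(resids, upper)},
        "species_by_resid": {int(r): s for r, s in species.items()},
        "binding_frame": cfg.binding_frame,
        "binding_leaflet": "upper",
        "protein_center_xy": [cfg.box_xy / 2.0, cfg.box_xy / 2.0],
        "deepest_resid": 1,
        "lipids_per_leaflet": cfg.lipids_per_leaflet,
        "species_counts_per_leaflet": largest_remainder_counts(
            cfg.lipids_per_leaflet, cfg.mole_fractions),
    }
    for sp_name in cfg.recruitment_bias:
        truth[f"enrichment_{sp_name}"] = ground_truth_enrichment(
            system, cfg, sp_name)
    return system, truth


def ground_truth_enrichment(
    system: MembraneSystem,
    cfg: SyntheticConfig,
    species: str,
    region_radius: float | None = None,
    last_k: int = 20,
) -> float:
    """Enrichment of ``species`` within the region radius of the protein axis,
    computed by direct arithmetic on the generator's own arrays (ground truth
    for the analysis pipeline to recover).

    Enrichment = (regional mole fraction among upper-leaflet lipids, averaged
    over the last ``last_k`` frames) / (bulk upper-leaflet mole fraction).
    """
    if region_radius is None:
        region_radius = cfg.protein_radius
    resids, _, markers = _lipid_groups(system)
    upper = system.coords[0, markers, 2] >= cfg.box_z / 2.0
    sp = system.lipid_species_by_resid.loc[resids].to_numpy()
    center = np.array([cfg.box_xy / 2.0, cfg.box_xy / 2.0])
    L = system.boxes[0, :2]
    sel = markers[upper]
    sp_u = sp[upper]
    bulk = float(np.mean(sp_u == species))
    if bulk == 0:
        raise ValueError(f"species {species} absent from the upper leaflet")
    fracs = []
    for f in range(max(0, system.n_frames - last_k), system.n_frames):
        d = system.coords[f, sel, :2] - center
        d -= L * np.round(d / L)
        inside = np.hypot(d[:, 0], d[:, 1]) <= region_radius
        if inside.sum() > 0:
            fracs.append(np.mean(sp_u[inside] == species))
    if not fracs:
        raise ValueError("region never populated")
    return float(np.mean(fracs) / bulk)


# -- plantable fixtures ----------------------------------------------------


def plant_hbond_geometry(
    system: MembraneSystem,
    n: int,
    frame: int = 0,
    seed: int = 0,
    angle_deg: float | None = None,
    distance: float = 2.9,
) -> tuple[MembraneSystem, list[tuple[int, int, int]]]:
    """Reposition ``n`` lipid headgroup oxygens so that exactly ``n``
    donor-acceptor pairs satisfy the hydrogen-bond criterion.

    Each planted pair has donor-acceptor distance ``distance`` (<= 3.0 Å) and
    a D-H...A angle of 180° by construction (or ``angle_deg`` for negative
    controls). After planting, any other donor/acceptor pair within 3.2 Å is
    pushed away so the planted count is exact. Returns the modified system and
    the planted (donor, hydrogen, acceptor) atom-index triples.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng([seed, 2])
    atoms = system.atoms
    donors = atoms.index[(atoms.segment == "protein") & (atoms.name == "ND")].to_numpy()
    hydros = atoms.index[(atoms.segment == "protein") & (atoms.name == "HD")].to_numpy()
    if n > len(donors):
        raise ValueError(f"requested {n} bonds but only {len(donors)} donors")
    lipid_o = atoms.index[(atoms.segment == "lipid") & (atoms.name == "OH2")].to_numpy()
    if n > len(lipid_o):
        raise ValueError(f"requested {n} bonds but only {len(lipid_o)} lipid acceptors")

    coords = system.coords.copy()
    pick_d = rng.choice(len(donors), size=n, replace=False) if n else np.array([], int)
    pick_a = rng.choice(len(lipid_o), size=n, replace=False) if n else np.array([], int)
    theta = 180.0 if angle_deg is None else angle_deg
    alpha = math.radians(180.0 - theta)
    planted = []
    for di, ai in zip(pick_d, pick_a):
        d_idx, h_idx, a_idx = int(donors[di]), int(hydros[di]), int(lipid_o[ai])
        d = coords[frame, d_idx]
        h = coords[frame, h_idx]
        u = (h - d) / np.linalg.norm(h - d)
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        v = math.cos(alpha) * u + math.sin(alpha) * perp
        ca = math.cos(alpha)
        rho = -ca + math.sqrt(max(ca * ca - 1.0 + distance * distance, 0.0))
        coords[frame, a_idx] = h + rho * v
        planted.append((d_idx, h_idx, a_idx))

    # push any accidental lipid acceptor out of range of every donor
    planted_acc = {a for _, _, a in planted}
    box = system.boxes[frame]
    all_acc = atoms.index[(atoms.element.isin(["N", "O"]))].to_numpy()
    for _ in range(20):
        dvec = minimum_image_displacement(
            coords[frame, donors][:, None, :], coords[frame, all_acc][None, :, :], box
        )
        dist = np.sqrt((dvec ** 2).sum(-1))
        bad_cols = set()
        for di, ai in zip(*np.where(dist <= 3.2)):
            a_idx = int(all_acc[ai])
            if a_idx in planted_acc or a_idx == int(donors[di]):
                continue
            if atoms.resid[a_idx] == atoms.resid[int(donors[di])]:
                continue
            if atoms.segment[a_idx] == "protein":
                continue  # protein-protein geometry is fixed and angle-rejected
            bad_cols.add(a_idx)
        if not bad_cols:
            break
        for a_idx in bad_cols:
            coords[frame, a_idx, 2] -= 5.0

    out = MembraneSystem(atoms=atoms.copy(), coords=coords, boxes=system.boxes.copy(),
                         times=system.times.copy(), registry=system.registry,
                         domains=dict(system.domains))
    return out, planted


def plant_defect_patch(
    system: MembraneSystem,
    frame: int,
    center: tuple[float, float],
    radius: float,
    leaflet: str = "upper",
) -> MembraneSystem:
    """Carve a circular hydrophobic-exposure patch into one leaflet.

    Lipids whose marker lies inside the disk keep their tail beads in place
    but have the top tail raised to the marker plane and their headgroup beads
    displaced radially out to the clearance ring; lipids whose headgroup disks
    would still overlap the patch are moved out entirely. The disk then
    exposes only hydrophobic beads (plus bare cells), which the defect
    detector should recover as a single component of area ~ pi r².
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = system.coords.copy()
    box = system.boxes[frame]
    L = box[:2]
    resids, groups, markers = _lipid_groups(system)
    mz = coords[frame, markers, 2]
    mid = mz.mean()
    in_leaflet = (mz >= mid) if leaflet == "upper" else (mz < mid)
    plane = mz[in_leaflet].mean()

    ctr = np.asarray(center, dtype=float)
    d = coords[frame, markers, :2] - ctr
    d -= L * np.round(d / L)
    r = np.hypot(d[:, 0], d[:, 1])

    # heads are recruited from a wider annulus than strictly necessary so the
    # clearance ring is densely populated and its coverage edge is sharp
    clearance = radius + _HEAD_RADIUS + 4.0
    atoms = system.atoms
    ring_heads: list[int] = []  # head beads to redistribute on the clearance ring
    for k in range(len(resids)):
        if not in_leaflet[k] or r[k] >= clearance:
            continue
        idx = groups[k]
        names = atoms.name.loc[idx].to_numpy()
        is_head = np.array([system.registry.for_resname(atoms.resname[idx[0]])
                            .atom_class(nm) == "hydrophilic" for nm in names])
        ring_heads.extend(int(i) for i in idx[is_head])
        if r[k] <= radius:
            # raise tails to the marker plane so the disk exposes them
            tail_idx = idx[~is_head]
            order = np.argsort(-coords[frame, tail_idx, 2]) if leaflet == "upper" \
                else np.argsort(coords[frame, tail_idx, 2])
            sgn = 1.0 if leaflet == "upper" else -1.0
            for rank, t in enumerate(tail_idx[order]):
                coords[frame, t, 2] = plane - sgn * 0.5 * rank

    # Redistribute displaced head beads evenly on a ring whose geometry makes
    # their disk coverage begin at the patch radius, so the uncovered area is
    # the planted disk to within grid resolution.
    m = len(ring_heads)
    if m > 0:
        r_ring = radius + _HEAD_RADIUS
        half_gap = np.pi * r_ring / m
        reach = np.sqrt(max(_HEAD_RADIUS**2 - half_gap**2, (0.5 * _HEAD_RADIUS) ** 2))
        # pull the ring in so that coverage begins at the patch radius even
        # midway between neighbouring head disks
        r_ring = radius + reach
        angles = 2 * np.pi * np.arange(m) / m
        for ang, i in zip(angles, ring_heads):
            coords[frame, i, 0] = ctr[0] + r_ring * np.cos(ang)
            coords[frame, i, 1] = ctr[1] + r_ring * np.sin(ang)
    # wrap back into the box
    coords[frame, :, 0] %= box[0]
    coords[frame, :, 1] %= box[1]
    return MembraneSystem(atoms=atoms.copy(), coords=coords, boxes=system.boxes.copy(),
                          times=system.times.copy(), registry=system.registry,
                          domains=dict(system.domains))


# -- output writing --------------------------------------------------------


def write_outputs(
    system: MembraneSystem,
    ground_truth: dict,
    outdir: str | Path,
    *,
    structure_formats: tuple[str, ...] = ("pdb",),
    trajectory_formats: tuple[str, ...] = ("xtc",),
) -> dict[str, Path]:
    """Write structure (PDB/GRO), trajectory (XTC/DCD), species YAML and the
    ground-truth JSON into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fmt in structure_formats:
        p = outdir / f"structure.{fmt}"
        write_system(system, p, None)
        paths[f"structure_{fmt}"] = p
    for fmt in trajectory_formats:
        p = outdir / f"trajectory.{fmt}"
        write_system(system, outdir / f"structure.{structure_formats[0]}", p)
        paths[f"trajectory_{fmt}"] = p
    sp_path = outdir / "species.yaml"
    save_species_config(system.registry, sp_path)
    paths["species"] = sp_path
    gt_path = outdir / "ground_truth.json"
    with open(gt_path, "w") as fh:
        json.dump(ground_truth, fh, indent=1, default=float)
    paths["ground_truth"] = gt_path
    return paths
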