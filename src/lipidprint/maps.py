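"""Cumulative 2D maps over the membrane plane.

Density maps count marker atoms per grid cell accumulated over a frame
window; height maps average the relative height z_f = z - z_o, where z_o is
the mean z of the selected atoms in the first frame of the window; charge
maps deposit each species' formal headgroup charge at its marker position.
Binning uses fractional (box-relative) coordinates with half-open bins so
the count-conservation identity holds exactly even when the box fluctuates;
areas are reported with the window-mean box. Protein masks rasterize the
protein's heavy atoms as xy disks onto an absolute-Å grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import MembraneSystem

__all__ = [
    "GridMap",
    "ProteinMask",
    "density_map",
    "height_map",
    "charge_map",
    "protein_mask",
    "rasterize_disks",
]

DEFAULT_BINS = 100


@dataclass
class GridMap:
    """2D binned field over the membrane plane (fractional coordinates)."""

    kind: str  # density | height | charge
    values: np.ndarray  # (bins, bins); height: mean z_f, NaN where unsampled
    samples: np.ndarray  # per-cell sample count
    bins: int
    window: tuple[int, int]
    leaflet: str
    species: str | None
    frames_accumulated: int
    mean_box: np.ndarray  # (3,) Å

    @property
    def cell_area(self) -> float:
        """Mean-box area of one cell, Å²."""
        return float(self.mean_box[0] * self.mean_box[1]) / self.bins**2


def _leaflet_resids(system: MembraneSystem, frame: int, leaflet: str) -> np.ndarray:
    markers = system.marker_index_by_resid
    z = system.coords[frame, markers.to_numpy(), 2]
    mask = z >= z.mean() if leaflet == "upper" else z < z.mean()
    return markers.index.to_numpy()[mask]


def _select_markers(system, frame, leaflet, species):
    markers = system.marker_index_by_resid
    resids = _leaflet_resids(system, frame, leaflet)
    if species is not None:
        sp = system.lipid_species_by_resid
        resids = resids[sp.loc[resids].to_numpy() == species]
    return markers.loc[resids].to_numpy()


def _frac_xy(system, frame, idx):
    xy = system.coords[frame, idx, :2]
    L = system.boxes[frame, :2]
    return (xy / L) % 1.0


def _hist2d(frac, bins, weights=None):
    h, _, _ = np.histogram2d(
        frac[:, 0], frac[:, 1], bins=bins, range=[[0, 1], [0, 1]], weights=weights
    )
    return h


def density_map(
    system: MembraneSystem,
    species: str | None,
    leaflet: str,
    window: tuple[int, int] | None = None,
    bins: int = DEFAULT_BINS,
) -> GridMap:
    """Cumulative marker-atom counts per cell over the window.

    Conservation: the cell sum equals (selected lipids) x (frames) exactly
    when the selection size is constant over the window.
    """
    if species is not None:
        system.registry.get(species)  # raises for unknown species
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    acc = np.zeros((bins, bins))
    for f in frames:
        idx = _select_markers(system, f, leaflet, species)
        if len(idx):
            acc += _hist2d(_frac_xy(system, f, idx), bins)
    return GridMap(kind="density", values=acc, samples=acc.copy(), bins=bins,
                   window=(frames.start, frames.stop), leaflet=leaflet,
                   species=species, frames_accumulated=len(frames),
                   mean_box=system.boxes[list(frames)].mean(axis=0))


def height_map(
    system: MembraneSystem,
    leaflet: str,
    window: tuple[int, int] | None = None,
    bins: int = DEFAULT_BINS,
    species: str | None = None,
) -> GridMap:
    """Mean relative height z_f = z - z_o per cell.

    z_o is the mean z of the selected marker atoms in the *first frame of the
    window*; cells with no samples are NaN (the map's "white patches").
    """
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    idx0 = _select_markers(system, frames.start, leaflet, species)
    if len(idx0) == 0:
        raise ValueError("empty selection")
    z_o = system.coords[frames.start, idx0, 2].mean()
    zsum = np.zeros((bins, bins))
    nsam = np.zeros((bins, bins))
    for f in frames:
        idx = _select_markers(system, f, leaflet, species)
        if len(idx) == 0:
            continue
        frac = _frac_xy(system, f, idx)
        zf = system.coords[f, idx, 2] - z_o
        zsum += _hist2d(frac, bins, weights=zf)
        nsam += _hist2d(frac, bins)
    with np.errstate(invalid="ignore"):
        values = np.where(nsam > 0, zsum / np.maximum(nsam, 1), np.nan)
    return GridMap(kind="height", values=values, samples=nsam, bins=bins,
                   window=(frames.start, frames.stop), leaflet=leaflet,
                   species=species, frames_accumulated=len(frames),
                   mean_box=system.boxes[list(frames)].mean(axis=0))


def charge_map(
    system: MembraneSystem,
    leaflet: str,
    window: tuple[int, int] | None = None,
    bins: int = DEFAULT_BINS,
) -> GridMap:
    """Cumulative formal headgroup charge (e) deposited at marker positions."""
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    sp_by_resid = system.lipid_species_by_resid
    charge_of = {s.name: float(s.charge) for s in system.registry}
    markers = system.marker_index_by_resid
    acc = np.zeros((bins, bins))
    for f in frames:
        resids = _leaflet_resids(system, f, leaflet)
        if len(resids) == 0:
            continue
        idx = markers.loc[resids].to_numpy()
        w = np.array([charge_of[sp_by_resid.loc[r]] for r in resids])
        acc += _hist2d(_frac_xy(system, f, idx), bins, weights=w)
    nsam = np.zeros_like(acc)
    return GridMap(kind="charge", values=acc, samples=nsam, bins=bins,
                   window=(frames.start, frames.stop), leaflet=leaflet,
                   species=None, frames_accumulated=len(frames),
                   mean_box=system.boxes[list(frames)].mean(axis=0))


# -- protein projection mask ----------------------------------------------


def rasterize_disks(
    xy: np.ndarray,
    radii: np.ndarray,
    box_xy: np.ndarray,
    nx: int,
    ny: int,
    z: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize disks onto a periodic (nx, ny) grid.

    Without z/labels, returns a boolean coverage mask. With them, returns an
    int grid where each covered cell carries the label of the *highest-z*
    atom covering it (painter's algorithm), 0 meaning uncovered.
    """
    cw, ch = box_xy[0] / nx, box_xy[1] / ny
    if z is None:
        grid = np.zeros((nx, ny), dtype=bool)
        order = range(len(xy))
    else:
        grid = np.zeros((nx, ny), dtype=np.int32)
        order = np.argsort(z, kind="stable")  # highest painted last
    for k in order:
        x, y = xy[k]
        r = radii[k]
        i0 = int(np.floor((x - r) / cw))
        i1 = int(np.floor((x + r) / cw))
        j0 = int(np.floor((y - r) / ch))
        j1 = int(np.floor((y + r) / ch))
        ii = np.arange(i0, i1 + 1)
        jj = np.arange(j0, j1 + 1)
        cx = (ii + 0.5) * cw - x
        cy = (jj + 0.5) * ch - y
        inside = (cx[:, None] ** 2 + cy[None, :] ** 2) <= r * r
        iw = ii % nx
        jw = jj % ny
        if z is None:
            grid[np.ix_(iw, jw)] |= inside
        else:
            sub = grid[np.ix_(iw, jw)]
            grid[np.ix_(iw, jw)] = np.where(inside, labels[k], sub)
    return grid


@dataclass
class ProteinMask:
    """Boolean grid of cells covered by the protein's xy projection."""

    mask: np.ndarray  # (nx, ny) bool
    cell_size: float  # Å (square cells)
    box_xy: np.ndarray  # (2,) Å
    window: tuple[int, int]

    @property
    def area(self) -> float:
        return float(self.mask.sum()) * self.cell_size**2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Membership of points (wrapped into the box) in the mask."""
        pts = np.atleast_2d(xy) % self.box_xy
        i = np.minimum((pts[:, 0] / self.cell_size).astype(int), self.mask.shape[0] - 1)
        j = np.minimum((pts[:, 1] / self.cell_size).astype(int), self.mask.shape[1] - 1)
        return self.mask[i, j]


def protein_mask(
    system: MembraneSystem,
    window: tuple[int, int] | int | None = None,
    cell_size: float = 1.0,
) -> ProteinMask:
    """Cells whose center lies inside the xy disk of any protein heavy atom
    (per-atom radius: explicit bead radius or the element vdW table). An
    integer selects a single frame; a range takes the union over frames."""
    heavy = system.protein_heavy_indices
    if len(heavy) == 0:
        raise ValueError("no protein atoms")
    if isinstance(window, (int, np.integer)):
        frames = range(int(window), int(window) + 1)
    else:
        frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    box_xy = system.boxes[frames.start, :2]
    nx = max(1, int(round(box_xy[0] / cell_size)))
    ny = max(1, int(round(box_xy[1] / cell_size)))
    radii = system.effective_radii(heavy)
    mask = np.zeros((nx, ny), dtype=bool)
    for f in frames:
        xy = system.coords[f, heavy, :2] % box_xy
        mask |= rasterize_disks(xy, radii, box_xy, nx, ny)
    return ProteinMask(mask=mask, cell_size=float(box_xy[0] / nx), box_xy=box_xy,
                       window=(frames.start, frames.stop))
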