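"""Grid-based lipid packing-defect detection.

The membrane surface of one leaflet is viewed from its water side: every
lipid heavy atom within 10 Å of the marker plane (on the water side of the
bilayer core) is rasterized as an xy disk, and each grid cell takes the
hydrophobicity class of the topmost atom covering it. Cells whose top atom
is hydrophobic expose the acyl-chain region; cells covered by nothing are
bare membrane surface and count toward defects as well (the bilayer is
periodic, so the whole grid is membrane footprint). Defects are maximal
connected components of such cells under periodic wrap-aware 8-connectivity;
components below a minimum area are discarded as speckle. "Local" defects
are those intersecting the protein's xy-projection mask, and the local
defect percentage is 100 x (defect area inside the mask) / (mask area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .blocks import block_standard_error, DEFAULT_BLOCKS
from .maps import ProteinMask, protein_mask, rasterize_disks
from .system import MembraneSystem

__all__ = [
    "ClassifiedGrid",
    "DefectComponent",
    "DefectStats",
    "classify_surface",
    "find_defects",
    "local_defect_percent",
    "defect_stats",
]

EMPTY, HYDROPHILIC, HYDROPHOBIC = 0, 1, 2
_DEPTH_WINDOW = 10.0  # Å below the marker plane still considered "surface"
DEFAULT_MIN_AREA = 5.0  # Å², speckle suppression


@dataclass
class ClassifiedGrid:
    """Per-cell surface classification of one leaflet at one frame."""

    labels: np.ndarray  # (nx, ny) int: 0 empty, 1 hydrophilic, 2 hydrophobic
    cell_size: float  # Å
    leaflet: str
    frame: int
    box_xy: np.ndarray

    @property
    def cell_area(self) -> float:
        return self.cell_size**2


@dataclass
class DefectComponent:
    """One connected hydrophobic-exposure patch."""

    frame: int
    leaflet: str
    cells: np.ndarray  # (k, 2) int cell indices
    area: float  # Å²
    centroid: tuple[float, float]  # Å, wrap-aware
    local: bool | None = None


@dataclass
class DefectStats:
    """Defect summary over a window: per-leaflet means and the local-% series."""

    per_leaflet: pd.DataFrame  # leaflet, mean_count, count_se, mean_area, area_se
    series: pd.DataFrame  # frame, leaflet, count, total_area [, local_pct]
    local_pct_bins: pd.DataFrame | None  # bin_start, bin_stop, mean_pct, se


def classify_surface(
    system: MembraneSystem,
    frame: int,
    leaflet: str,
    cell_size: float = 1.0,
) -> ClassifiedGrid:
    """Classify each grid cell as hydrophilic, hydrophobic or empty."""
    markers = system.marker_index_by_resid
    z_m = system.coords[frame, markers.to_numpy(), 2]
    mid = z_m.mean()
    in_leaf = z_m >= mid if leaflet == "upper" else z_m < mid
    resids = set(int(r) for r in markers.index.to_numpy()[in_leaf])
    if not resids:
        raise ValueError(f"leaflet {leaflet!r} has no lipids at frame {frame}")
    plane = z_m[in_leaf].mean()

    lipid = system.atoms[system.atoms.segment == "lipid"]
    sel = lipid[lipid.resid.isin(resids)]
    classes = np.empty(len(sel), dtype=np.int32)
    for k, (idx, row) in enumerate(sel.iterrows()):
        sp = system.registry.for_resname(row.resname)
        classes[k] = HYDROPHILIC if sp.atom_class(row["name"]) == "hydrophilic" \
            else HYDROPHOBIC

    idxs = sel.index.to_numpy()
    z = system.coords[frame, idxs, 2]
    if leaflet == "upper":
        keep = z >= plane - _DEPTH_WINDOW
        z_view = z
    else:
        keep = z <= plane + _DEPTH_WINDOW
        z_view = -z  # mirrored so "topmost from the water side" is max
    idxs, z_view, classes = idxs[keep], z_view[keep], classes[keep]

    box_xy = system.boxes[frame, :2]
    nx = max(1, int(round(box_xy[0] / cell_size)))
    ny = max(1, int(round(box_xy[1] / cell_size)))
    xy = system.coords[frame, idxs, :2] % box_xy
    radii = system.effective_radii(idxs)
    labels = rasterize_disks(xy, radii, box_xy, nx, ny, z=z_view, labels=classes)
    return ClassifiedGrid(labels=labels, cell_size=float(box_xy[0] / nx),
                          leaflet=leaflet, frame=frame, box_xy=box_xy)


def _periodic_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labels with periodic wrap-aware connectivity."""
    structure = np.ones((3, 3), bool) if connectivity == 8 else \
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return lab
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    nx, ny = mask.shape
    offs = [-1, 0, 1] if connectivity == 8 else [0]
    # seam between row nx-1 and row 0, and column ny-1 and column 0
    for j in range(ny):
        a = lab[nx - 1, j]
        if not a:
            continue
        for dj in offs:
            b = lab[0, (j + dj) % ny]
            if b:
                union(a, b)
    for i in range(nx):
        a = lab[i, ny - 1]
        if not a:
            continue
        for di in offs:
            b = lab[(i + di) % nx, 0]
            if b:
                union(a, b)
    remap = np.array([find(a) for a in range(n + 1)])
    return remap[lab]


def _circular_centroid(cells: np.ndarray, shape, cell_size: float):
    """Wrap-aware centroid of a cell set, in Å."""
    out = []
    for axis, n in enumerate(shape):
        theta = cells[:, axis] * 2 * np.pi / n
        ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) % (2 * np.pi)
        out.append((ang * n / (2 * np.pi) + 0.5) * cell_size)
    return tuple(out)


def find_defects(
    grid: ClassifiedGrid,
    connectivity: int = 8,
    min_area: float = DEFAULT_MIN_AREA,
) -> list[DefectComponent]:
    """Label connected hydrophobic-exposure components on a classified grid.

    Defect cells are hydrophobic-topped cells plus uncovered (empty) cells.
    Components below ``min_area`` Å² are discarded; the result is ordered by
    (descending area, centroid).
    """
    mask = (grid.labels == HYDROPHOBIC) | (grid.labels == EMPTY)
    lab = _periodic_label(mask, connectivity)
    comps = []
    for value in np.unique(lab):
        if value == 0:
            continue
        cells = np.argwhere(lab == value)
        area = len(cells) * grid.cell_area
        if area < min_area:
            continue
        comps.append(DefectComponent(
            frame=grid.frame, leaflet=grid.leaflet, cells=cells, area=area,
            centroid=_circular_centroid(cells, grid.labels.shape, grid.cell_size),
        ))
    comps.sort(key=lambda c: (-c.area, c.centroid))
    return comps


def local_defect_percent(
    components: list[DefectComponent], mask: ProteinMask
) -> float:
    """100 x (defect cell area intersecting the protein mask) / (mask area)."""
    if mask.area <= 0:
        raise ValueError("zero-area protein mask")
    inside_cells = 0
    for comp in components:
        if comp.cells.size == 0:
            continue
        if mask.mask.shape != _expected_shape(comp, mask):
            raise ValueError("protein mask and defect grid geometries differ")
        inside = mask.mask[comp.cells[:, 0], comp.cells[:, 1]]
        inside_cells += int(inside.sum())
        comp.local = bool(inside.any()) if comp.local is None else comp.local
    cell_area = mask.cell_size**2
    return 100.0 * inside_cells * cell_area / mask.area


def _expected_shape(comp: DefectComponent, mask: ProteinMask):
    return mask.mask.shape


def defect_stats(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    leaflets: tuple[str, ...] = ("upper", "lower"),
    cell_size: float = 1.0,
    min_area: float = DEFAULT_MIN_AREA,
    connectivity: int = 8,
    n_blocks: int = DEFAULT_BLOCKS,
    local_leaflet: str | None = None,
    local_bin_frames: int = 100,
) -> DefectStats:
    """Per-frame defect counts and total areas per leaflet, with window means
    and block SEs; optionally the local-% series (vs the per-frame protein
    mask) for one leaflet, binned into ``local_bin_frames``-frame windows."""
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    rows = []
    local_rows = []
    for f in frames:
        pm = protein_mask(system, f, cell_size) if local_leaflet else None
        for leaf in leaflets:
            grid = classify_surface(system, f, leaf, cell_size)
            comps = find_defects(grid, connectivity, min_area)
            row = {"frame": f, "leaflet": leaf, "count": len(comps),
                   "total_area": sum(c.area for c in comps)}
            if local_leaflet == leaf:
                pct = local_defect_percent(comps, pm)
                row["local_pct"] = pct
                local_rows.append((f, pct))
            rows.append(row)
    series = pd.DataFrame(rows)
    per_leaflet = []
    for leaf in leaflets:
        sub = series[series.leaflet == leaf]
        per_leaflet.append({
            "leaflet": leaf,
            "mean_count": sub["count"].mean(),
            "count_se": block_standard_error(sub["count"].to_numpy(), n_blocks),
            "mean_area": sub.total_area.mean(),
            "area_se": block_standard_error(sub.total_area.to_numpy(), n_blocks),
        })
    local_bins = None
    if local_rows:
        lr = pd.DataFrame(local_rows, columns=["frame", "pct"])
        lr["bin"] = (lr.frame - frames.start) // local_bin_frames
        agg = []
        for b, sub in lr.groupby("bin"):
            agg.append({
                "bin_start": frames.start + int(b) * local_bin_frames,
                "bin_stop": min(frames.start + (int(b) + 1) * local_bin_frames,
                                frames.stop),
                "mean_pct": sub.pct.mean(),
                "se": block_standard_error(sub.pct.to_numpy(), n_blocks)
                if len(sub) > 1 else 0.0,
            })
        local_bins = pd.DataFrame(agg)
    return DefectStats(per_leaflet=pd.DataFrame(per_leaflet), series=series,
                       local_pct_bins=local_bins)
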