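"""Data model and I/O for protein-membrane trajectories.

The central container is :class:`MembraneSystem`: an atom table (pandas), a
dense coordinate array in Å (frames x atoms x 3), per-frame orthorhombic box
lengths and time stamps in ns, a lipid :class:`~lipidprint.species.SpeciesRegistry`
and a protein domain table. File I/O (PDB/GRO structures; XTC/DCD/multi-model
PDB trajectories) goes through MDAnalysis; everything downstream operates on
plain numpy arrays.

Leaflets are assigned per frame from the headgroup marker atoms: the midplane
is the mean marker z and a lipid is *upper* when its marker sits at or above
it. The binding leaflet is detected as the leaflet holding the majority of the
marker atoms within the contact cutoff at the first frame any protein Cα comes
within that cutoff (12 Å by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .species import SpeciesRegistry, load_species_config

__all__ = [
    "MembraneSystem",
    "LeafletAssignment",
    "BindingEvent",
    "load_system",
    "write_system",
    "minimal_image_distance",
    "minimum_image_displacement",
    "assign_leaflets",
    "detect_binding_leaflet",
    "MLKL_DOMAINS",
    "CONTACT_CUTOFF",
]

#: Default protein-lipid contact cutoff in Å (Cα or heavy atom to marker atom).
CONTACT_CUTOFF = 12.0

#: MLKL domain table: four-helical bundle, brace helices, pseudo-kinase domain.
#: Residues in the gaps (122-132, 176-192) are labelled "linker" and excluded
#: from per-domain metrics.
MLKL_DOMAINS: dict[str, tuple[int, int]] = {
    "4HB": (1, 121),
    "brace": (133, 175),
    "PsK": (193, 459),
}

_WATER_RESNAMES = {"TIP3", "TIP3P", "HOH", "WAT", "SOL", "W", "SPC", "TIP4"}
_ION_RESNAMES = {"NA", "CL", "K", "SOD", "CLA", "POT", "MG", "CAL", "CA2", "ZN"}
_AMINO_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

#: van der Waals radii (Å) used for disk rasterization of atomistic input.
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}
_DEFAULT_VDW = 1.7


def element_from_name(name: str) -> str:
    """Guess an element symbol from an atom name (first alphabetic character)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass
class LeafletAssignment:
    """Per-frame leaflet partition of the lipid residues."""

    frame: int
    labels: dict[int, str]  # lipid resid -> "upper" | "lower"
    midplane: float  # Å

    def resids(self, leaflet: str) -> list[int]:
        return [r for r, lab in self.labels.items() if lab == leaflet]


@dataclass
class BindingEvent:
    """Outcome of binding-leaflet detection."""

    leaflet: str
    frame: int


@dataclass
class MembraneSystem:
    """Topology + trajectory container for all analyses.

    Attributes
    ----------
    atoms
        DataFrame indexed 0..N-1 with columns ``name``, ``resname``, ``resid``,
        ``segment`` (protein|lipid|solvent|ion), ``element`` and optionally
        ``radius`` (Å, NaN where unknown).
    coords
        float64 array of shape (n_frames, n_atoms, 3), Å.
    boxes
        float64 array of shape (n_frames, 3): orthorhombic box lengths, Å.
    times
        float64 array of per-frame time stamps, ns.
    registry
        Lipid species registry.
    domains
        Mapping domain label -> inclusive residue-id range for the protein.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    registry: SpeciesRegistry
    domains: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(MLKL_DOMAINS))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        if self.coords.shape[0] != self.boxes.shape[0] != self.times.shape[0]:
            raise ValueError("coords, boxes and times disagree on frame count")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"atom count mismatch: table has {len(self.atoms)} atoms, "
                f"frames have {self.coords.shape[1]}"
            )
        if np.any(self.boxes <= 0):
            raise ValueError("box lengths must be strictly positive")
        self._check_species_coverage()
        self._cache: dict[str, object] = {}

    # -- bookkeeping -------------------------------------------------------

    def _check_species_coverage(self) -> None:
        lipid = self.atoms[self.atoms.segment == "lipid"]
        unknown = sorted(
            rn for rn in lipid.resname.unique() if self.registry.for_resname(rn) is None
        )
        if unknown:
            raise ValueError(f"unclassifiable lipid residue names: {unknown}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def _cached(self, key: str, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def lipid_species_by_resid(self) -> pd.Series:
        """Map lipid resid -> species name."""

        def build():
            lipid = self.atoms[self.atoms.segment == "lipid"]
            per_res = lipid.groupby("resid").resname.first()
            return per_res.map(lambda rn: self.registry.for_resname(rn).name)

        return self._cached("species_by_resid", build)

    @property
    def marker_index_by_resid(self) -> pd.Series:
        """Map lipid resid -> atom index of its headgroup marker atom."""

        def build():
            lipid = self.atoms[self.atoms.segment == "lipid"]
            rows = {}
            for resid, grp in lipid.groupby("resid"):
                sp = self.registry.for_resname(grp.resname.iloc[0])
                sel = grp.index[grp.name == sp.marker]
                if len(sel) != 1:
                    raise ValueError(
                        f"lipid residue {resid} ({sp.name}): expected exactly one "
                        f"marker atom {sp.marker!r}, found {len(sel)}"
                    )
                rows[resid] = int(sel[0])
            return pd.Series(rows, dtype=np.int64).sort_index()

        return self._cached("marker_by_resid", build)

    def marker_indices(self, species: str | None = None) -> np.ndarray:
        """Atom indices of marker atoms, optionally restricted to one species."""
        markers = self.marker_index_by_resid
        if species is None:
            return markers.to_numpy()
        sp = self.lipid_species_by_resid
        return markers[sp[sp == species].index].to_numpy()

    @property
    def protein_ca_indices(self) -> np.ndarray:
        def build():
            m = (self.atoms.segment == "protein") & (self.atoms.name == "CA")
            return self.atoms.index[m].to_numpy()

        return self._cached("prot_ca", build)

    @property
    def protein_heavy_indices(self) -> np.ndarray:
        def build():
            m = (self.atoms.segment == "protein") & (self.atoms.element != "H")
            return self.atoms.index[m].to_numpy()

        return self._cached("prot_heavy", build)

    @property
    def protein_resids(self) -> np.ndarray:
        def build():
            return np.sort(self.atoms.loc[self.atoms.segment == "protein", "resid"].unique())

        return self._cached("prot_resids", build)

    def domain_of(self, resid: int) -> str:
        for label, (lo, hi) in self.domains.items():
            if lo <= resid <= hi:
                return label
        return "linker"

    def ca_index_of_residue(self, resid: int) -> int:
        m = (
            (self.atoms.segment == "protein")
            & (self.atoms.resid == resid)
            & (self.atoms.name == "CA")
        )
        idx = self.atoms.index[m]
        if len(idx) == 0:
            raise KeyError(f"no Cα for protein residue {resid}")
        return int(idx[0])

    def effective_radii(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Per-atom rasterization radius: explicit ``radius`` column where set,
        element vdW radius otherwise."""
        atoms = self.atoms if indices is None else self.atoms.loc[indices]
        vdw = atoms.element.map(lambda e: VDW_RADII.get(e, _DEFAULT_VDW)).to_numpy(float)
        if "radius" in atoms.columns:
            explicit = atoms.radius.to_numpy(float)
            vdw = np.where(np.isfinite(explicit), explicit, vdw)
        return vdw

    def frame_range(self, window: tuple[int, int] | None) -> range:
        """Half-open [start, stop) frame window; None means all frames."""
        if window is None:
            return range(self.n_frames)
        start, stop = window
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(
                f"window {window} outside trajectory of {self.n_frames} frames"
            )
        return range(start, stop)


# -- periodic geometry -----------------------------------------------------


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a for an orthorhombic box (broadcasts)."""
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ValueError("box lengths must be strictly positive")
    d = np.asarray(b, dtype=np.float64) - np.asarray(a, dtype=np.float64)
    return d - box * np.round(d / box)


def minimal_image_distance(a, b, box) -> float | np.ndarray:
    """Minimum distance between ``a`` and ``b`` over all periodic images."""
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def pair_distances(A: np.ndarray, B: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(A), len(B)) matrix of minimum-image distances."""
    d = B[None, :, :] - A[:, None, :]
    box = np.asarray(box, dtype=np.float64)
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# -- leaflet logic ---------------------------------------------------------


def assign_leaflets(system: MembraneSystem, frame: int) -> LeafletAssignment:
    """Partition lipids into upper/lower leaflet by marker z vs. the midplane.

    The midplane is the mean z of all marker atoms at this frame; a lipid is
    *upper* when its marker z is >= the midplane. Deterministic; if every
    marker sits exactly at the midplane a warning is emitted and all lipids
    are labelled upper.
    """
    markers = system.marker_index_by_resid
    if len(markers) == 0:
        raise ValueError("system has no lipids")
    z = system.coords[frame, markers.to_numpy(), 2]
    midplane = float(z.mean())
    upper = z >= midplane
    if upper.all() or (~upper).all():
        warnings.warn(
            f"frame {frame}: degenerate leaflet assignment (all lipids on one side)",
            stacklevel=2,
        )
    labels = {
        int(resid): ("upper" if up else "lower")
        for resid, up in zip(markers.index, upper)
    }
    return LeafletAssignment(frame=frame, labels=labels, midplane=midplane)


def detect_binding_leaflet(
    system: MembraneSystem,
    window: tuple[int, int] | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> BindingEvent | None:
    """Find the first frame of protein-membrane contact and the binding leaflet.

    A contact exists when any protein Cα lies within ``cutoff`` of any lipid
    marker atom (minimum image). The binding leaflet is the leaflet of the
    majority of marker atoms within the cutoff at that frame (ties break to
    upper). Returns None if the protein never makes contact in the window.
    """
    frames = system.frame_range(window)
    if len(frames) == 0:
        raise ValueError("empty window")
    ca = system.protein_ca_indices
    if len(ca) == 0:
        raise ValueError("no protein present")
    markers = system.marker_index_by_resid
    midx = markers.to_numpy()
    for f in frames:
        if cutoff <= 0:
            continue
        D = pair_distances(system.coords[f, ca], system.coords[f, midx], system.boxes[f])
        in_contact = (D <= cutoff).any(axis=0)
        if in_contact.any():
            assignment = assign_leaflets(system, f)
            labs = [assignment.labels[int(r)] for r in markers.index[in_contact]]
            n_up = sum(1 for x in labs if x == "upper")
            leaflet = "upper" if n_up >= len(labs) - n_up else "lower"
            return BindingEvent(leaflet=leaflet, frame=f)
    return None


# -- file I/O --------------------------------------------------------------


def _classify_segment(resname: str, registry: SpeciesRegistry) -> str | None:
    if registry.for_resname(resname) is not None:
        return "lipid"
    if resname in _AMINO_RESNAMES:
        return "protein"
    if resname in _WATER_RESNAMES:
        return "solvent"
    if resname in _ION_RESNAMES:
        return "ion"
    return None


def load_system(
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    species_config: str | Path | SpeciesRegistry | None = None,
    *,
    domains: dict[str, tuple[int, int]] | None = None,
    radii: str = "element",
) -> MembraneSystem:
    """Load a structure (+ optional trajectory) into a :class:`MembraneSystem`.

    Parameters
    ----------
    structure_path
        PDB or GRO file. GRO nm coordinates are converted to Å on load
        (MDAnalysis convention).
    trajectory_path
        XTC, DCD or multi-model PDB trajectory; omit to use the structure's
        own frames.
    species_config
        YAML path or an in-memory :class:`SpeciesRegistry`.
    radii
        ``"element"`` (vdW table) or ``"occupancy"`` to read per-atom
        rasterization radii from the PDB occupancy column (used by the
        synthetic writer to round-trip coarse bead radii).
    """
    import MDAnalysis as mda

    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(f"structure not found: {structure_path}")
    if trajectory_path is not None and not Path(trajectory_path).exists():
        raise FileNotFoundError(f"trajectory not found: {trajectory_path}")
    if species_config is None:
        raise ValueError("a species configuration is required")
    if isinstance(species_config, SpeciesRegistry):
        registry = species_config
    else:
        registry = load_species_config(species_config)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(str(structure_path))
            else:
                u = mda.Universe(str(structure_path), str(trajectory_path))
        except OSError as exc:
            raise exc
        except Exception as exc:  # MDAnalysis raises various types here
            if "atom" in str(exc).lower() and "number" in str(exc).lower():
                raise ValueError(f"atom count mismatch: {exc}") from exc
            raise

    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        elements = [str(e).capitalize().upper() for e in u.atoms.elements]
    except Exception:
        elements = [element_from_name(n) for n in names]

    segments = []
    unknown: set[str] = set()
    for rn in resnames:
        seg = _classify_segment(rn, registry)
        if seg is None:
            unknown.add(rn)
            seg = "unknown"
        segments.append(seg)
    if unknown:
        raise ValueError(f"unclassifiable residue names: {sorted(unknown)}")

    atoms = pd.DataFrame(
        {
            "name": names,
            "resname": resnames,
            "resid": resids.astype(np.int64),
            "segment": segments,
            "element": elements,
        }
    )
    if radii == "occupancy":
        try:
            occ = u.atoms.occupancies.astype(float)
            atoms["radius"] = np.where(occ > 0, occ, np.nan)
        except Exception:
            pass
    elif radii != "element":
        raise ValueError(f"radii must be 'element' or 'occupancy', got {radii!r}")

    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no dt information.*")
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or np.all(dims[:3] == 0):
                raise ValueError("trajectory frame has no box information")
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise ValueError(
                    f"triclinic box (angles {dims[3:]}) not supported; "
                    "orthorhombic boxes only"
                )
            coords.append(ts.positions.astype(np.float64).copy())
            boxes.append(dims[:3].astype(np.float64).copy())
            times.append(ts.time / 1000.0)  # ps -> ns

    return MembraneSystem(
        atoms=atoms,
        coords=np.stack(coords),
        boxes=np.stack(boxes),
        times=np.asarray(times),
        registry=registry,
        domains=dict(domains) if domains is not None else dict(MLKL_DOMAINS),
    )


def write_system(
    system: MembraneSystem,
    structure_path: str | Path,
    trajectory_path: str | Path | None = None,
    *,
    radii_as_occupancy: bool = True,
) -> None:
    """Write a system as a PDB/GRO structure plus an optional XTC/DCD trajectory.

    When writing PDB structures, per-atom rasterization radii (if present) are
    stored in the occupancy column so that :func:`load_system` with
    ``radii="occupancy"`` round-trips them.
    """
    import MDAnalysis as mda

    n = system.n_atoms
    resid_codes, resid_index = np.unique(
        system.atoms.resid.to_numpy(), return_inverse=True
    )
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(resid_codes),
        atom_resindex=resid_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", system.atoms.name.to_numpy())
    u.add_TopologyAttr("elements", system.atoms.element.to_numpy())
    res_order = pd.DataFrame(
        {"resid": system.atoms.resid, "resname": system.atoms.resname}
    ).drop_duplicates("resid").set_index("resid").loc[resid_codes]
    u.add_TopologyAttr("resids", resid_codes)
    u.add_TopologyAttr("resnames", res_order.resname.to_numpy())
    if radii_as_occupancy and "radius" in system.atoms.columns:
        occ = system.atoms.radius.to_numpy(float)
        occ = np.where(np.isfinite(occ), occ, 0.0)
        u.add_TopologyAttr("occupancies", occ)

    structure_path = Path(structure_path)
    dims0 = np.concatenate([system.boxes[0], [90.0, 90.0, 90.0]])
    u.atoms.positions = system.coords[0].astype(np.float32)
    u.dimensions = dims0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(structure_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n_atoms=n) as w:
                for f in range(system.n_frames):
                    u.atoms.positions = system.coords[f].astype(np.float32)
                    u.dimensions = np.concatenate([system.boxes[f], [90, 90, 90]])
                    u.trajectory.ts.time = system.times[f] * 1000.0  # ns -> ps
                    u.trajectory.ts.frame = f
                    w.write(u.atoms)
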