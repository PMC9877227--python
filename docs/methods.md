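# Methods

This note documents the models, conventions and numerical choices behind
`lipidprint`, and what the synthetic generator does and does not emulate.

## Data model and geometry

A trajectory is held as an atom table (name, residue, segment tag, element,
optional per-atom rasterization radius), a dense float64 coordinate array in
Å, per-frame orthorhombic box lengths and time stamps in ns. File I/O goes
through MDAnalysis (PDB/GRO structures; XTC/DCD/multi-model-PDB
trajectories); GRO nm coordinates are converted to Å on load. Triclinic
boxes are rejected with a clear error rather than approximated: every cutoff
analysis relies on the orthorhombic minimum-image convention
(`d -= L·round(d/L)` per axis), which is exact there and is verified in the
tests against a 27-image brute-force enumeration.

Lipid species are configured, not hardcoded: each species names its residue
aliases, a single headgroup **marker atom** (phosphorus for phospholipids,
the O3 hydroxyl oxygen for cholesterol), disjoint hydrophilic/hydrophobic
heavy-atom sets, a formal headgroup charge and a mole fraction. The default
registry is the five-species plasma-membrane model
DOPC:Chol:DOPE:PIP:PIP₂ = 40:32:20:4:4 mol% with formal charges
0/0/0/−3/−5 e. The formal charges are configuration, not constants, since
charge maps could equally be built from full partial-charge sets.

**Leaflets** are assigned per frame: the midplane is the mean marker z and a
lipid is *upper* when its marker z ≥ midplane. Flips are reported, not
smoothed — at the nanosecond frame spacing the analyses assume, genuine
flip-flop is rare, and smoothing would hide registration errors. The
**binding leaflet** is decided at the first frame any protein Cα comes
within the contact cutoff (12 Å, closed interval) of any marker atom, by
majority vote among the markers inside the cutoff (ties go to upper). The
majority-vote rule is this package's own operationalization; nothing in the
underlying observables depends on it once a leaflet is fixed.

Protein domains are inclusive residue-id ranges; the default table is the
MLKL monomer's 4HB (1–121), brace (133–175) and pseudo-kinase (193–459).
Residues in the gaps (122–132, 176–192) are labelled `linker` and excluded
from per-domain metrics rather than silently attached to a neighbour.

## Contacts, depth, RMSD

Two contact definitions coexist deliberately: per-residue contact frequency
uses the residue **Cα** against binding-leaflet markers, while
domain × species counts use **all protein heavy atoms** against the markers
of each species. Both are closed-interval (≤ cutoff). Insertion depth is the
window mean of (marker-plane z − Cα z), sign-oriented so positive means
inserted past the plane toward the core; the deepest residue is the argmax
with ties broken to the lowest residue id, and only residues that ever enter
the contact cutoff are profiled. Whether a COM–membrane distance should be a
z-projection or a full 3D distance is genuinely ambiguous; the z-projection
to the mean marker plane is used because bound-state distances then plateau
near zero, which is the behaviour the observable is meant to expose.

RMSD and RMSF operate on Cα coordinates after least-squares rigid-body
superposition (Kabsch, with the determinant correction for reflections).
RMSF superposes all frames onto the first frame, recomputes the mean
structure, re-superposes onto that mean and measures fluctuations about it.
The implementation is cross-checked in the tests against
`MDAnalysis.analysis.rms` as an independent route.

All window statistics carry standard errors from **block averages**: the
window is split into 5 (configurable) contiguous blocks and
SE = SD(block means)/√n_blocks, with SD using n−1 degrees of freedom. A
constant series yields SE = 0 exactly.

## Hydrogen bonds

The criterion is geometric: donor–acceptor heavy-atom distance ≤ 3.2 Å and
a D–H⋯A angle within 30° of linearity, i.e. the angle at the hydrogen
≥ 150°. The angle-cutoff convention ("30°" measured as deviation from
linear) matches the common analysis-tool reading of that parameter. Donors
are N/O atoms with a bonded hydrogen — resolved by covalent distance
(< 1.2 Å) for the protein and by name-pairing in the species configuration
for lipids; acceptors are all protein/lipid N/O atoms; intra-residue pairs
are excluded. Detection is per frame with no occupancy smoothing. Counts are
(D,H,A) triples; unique (D,A) pair counts are reported alongside because
the two conventions differ when one donor carries two hydrogens.

## Surface maps

Density, height and charge maps bin marker atoms in **fractional**
(box-relative) xy coordinates with half-open bins. Fractional binning is
what makes the conservation identity — Σ cells = selected lipids × frames —
exact even under a fluctuating (semi-isotropically coupled) box; physical
areas are reported with the window-mean box. Default grid 100×100 (~1.7 Å
cells at the full 173 Å scale). Height maps use z_f = z − z_o with z_o the
mean z of the selected atoms in the first frame of the window; cells with no
samples are NaN, reproducing the "white patches" convention for absent
headgroups. Charge maps deposit the species' formal charge at the marker.
One sample per frame at the frame interval (nominally 1 ns) implements the
cumulative-accumulation convention.

The protein mask covers every cell whose center lies in the xy disk of a
protein heavy atom (explicit bead radius where present, element vdW radius
otherwise); window masks are unions over frames.

## Packing defects

The detector reproduces an image-contour method without the rendering step:
instead of drawing the leaflet and contouring pixels, each lipid heavy atom
within 10 Å of the marker plane (on the water side) is rasterized directly
as an xy disk at 1 Å/cell (configurable, emulating pixel size), and each
cell takes the class of the **topmost** atom covering it — hydrophilic
headgroup or hydrophobic tail. The non-binding leaflet is processed after
z-mirroring. Cells covered by nothing are bare surface; since the bilayer is
periodic and spans the whole box, the entire grid is membrane footprint and
uncovered cells join the hydrophobic-exposure class for defect purposes.
Defect components are maximal connected sets under periodic wrap-aware
8-connectivity (scipy labeling plus a union-find merge across the box
seams), with components under 5 Å² discarded as speckle (configurable to 0).
Only exposure defects are computed — no deep/shallow subclasses. Because the
original method's pixel-to-Å calibration is not recoverable, absolute areas
are validated against planted fixtures of known area rather than against
published magnitudes; a planted 100 Å² disk is recovered within ±10% at
1 Å cells, and halving the cell size moves the measured area by < 10%.

The local defect percentage is
`100 × (defect cell area inside the protein mask) / (mask area)`; with the
mask and defect grid on the same lattice the 100 Å²-in-400 Å² fixture gives
exactly 25.0.

## RDFs and the fingerprint

g(r) is the standard pair-distance histogram with minimum-image distances,
normalized per frame by the shell volume 4πr²dr (r at the bin center) and
the target number density in the box, averaged over the window. The bin-center
shell approximation keeps the single-pair closed form
1/(4πr²·dr·ρ) exact by construction and deviates from the exact shell
volume by O((dr/r)²), far below the estimator's statistical noise. For
leaflet-restricted lipid–lipid RDFs a lateral (2D) variant normalizing by
2πr·dr and surface density is available behind a flag; 3D is the default
since the in-plane normalization convention is ambiguous in the field.
r_max is capped at half the smallest box length. Protein-anchored RDFs
default to the Cα of the deepest inserted residue, overridable by residue
id.

The fingerprint counts binding-leaflet lipids whose marker falls in a
region — the window-union protein mask ("underneath the protein" in the
projection sense), a radial cutoff about the protein axis (computed as a
wrap-safe circular mean of the protein heavy atoms), or the whole leaflet —
and reports per-species mean counts, regional mole fractions, all pairwise
ratios, and enrichment = regional fraction / bulk leaflet fraction, with
block SEs. `fingerprint_delta` is pure bookkeeping over two reports sharing
a region definition.

## The synthetic generator

The generator emulates exactly the features the analyses consume, not
membrane physics. Lipids are coarse bead clusters: a phospholipid is a P
marker with two headgroup oxygens stacked above it (toward water) and four
tail carbons below; cholesterol is an O3 marker with three tail carbons.
Beads carry explicit rasterization radii (6 Å heads, 5 Å tails) sized so
that headgroup disks tile the leaflet at the lattice spacing (~7.1 Å,
49.9 Å² per lipid — the areal density implied by 600 lipids per leaflet in
a 173 Å box); an intact bilayer therefore classifies as a fully hydrophilic
surface, which is the correct null for the defect detector. Species counts
come from largest-remainder rounding of the mole fractions, so per-species
counts are exact test targets (600 → 240/192/120/24/24). The lattice is a
rectangular grid with an evenly stretched last row, leaving no unfilled
sites that would read as spurious defects.

Dynamics are kinematic: lipids move as rigid units with 2D Gaussian steps of
variance 2DΔt per axis (default D = 1 Å²/ns, Δt = 1 ns — a typical lateral
diffusion scale), periodic wrapping, and non-cumulative z jitter
(σ = 0.15 Å). The pseudo-protein is a rigid sunflower disk of residues (one
Cα plus one donor N–H pair and one acceptor O per residue) that descends
linearly from 40 Å above the marker plane to a bound height of 6 Å at the
binding frame and is static afterwards; residue 1 hangs below the Cα plane
so that a known residue is the deepest inserted one. Recruitment is a drift,
not an energy model: after the binding frame, biased species inside a
capture radius (30 Å) step toward the protein axis at the configured speed,
stopping at a 2 Å core radius. Ground truth — leaflet labels, species
census, first-contact frame, planted bond triples and patch geometry, and
the steady-state enrichment computed by direct arithmetic on the generator's
own arrays — is emitted alongside the trajectory; downstream tests compare
the analysis pipeline's output against these tables, keeping the two code
paths independent.

Planted hydrogen bonds reposition lipid headgroup oxygens along the
donor→hydrogen axis (D–A = 2.9 Å, ∠DHA = 180°, or a forced angle for
negative controls) and then push any accidental in-range acceptor away, so
the planted count is exact. Planted defect patches raise the tails of
in-disk lipids to the marker plane and redistribute the displaced headgroup
beads evenly on a clearance ring whose radius is chosen so disk coverage
begins at the patch boundary; the exposed area then equals πr² to within
grid resolution.

What the generator does **not** emulate — conformational dynamics, a force
field, water, membrane undulations, cooperative lipid–lipid interactions —
bounds what passing tests show: they validate the *measurement machinery*
(geometry, counting, normalization, labeling, I/O round trips) on data with
known answers, not the biophysics of any particular system. On real
trajectories the same code paths apply unchanged, but their outputs inherit
the sampling and force-field caveats of the input.

## Pipeline, sizes and determinism

The pipeline runs load/generate → binding detection → contacts/depth/RMSD →
hydrogen bonds → maps → defects → RDF/fingerprint, with analysis windows
expressed relative to the detected binding frame so early-vs-late
comparisons need no hardcoded frame numbers. Stage failures are recorded in
the manifest without corrupting earlier artifacts; runs are bit-reproducible
for a fixed config and seed, identified by a hash over all parameters except
the output location. If binding never occurs, binding-dependent stages are
skipped with explicit notices.

Tests and the acceptance script run at a reduced scale chosen to preserve
the full-scale areal density: 64 lipids per leaflet in a 56.5 Å box, 100–500
frames, with 150-frame runs across 20 seeds for the sign-consistency check.
These sizes give comfortable statistics for every planted effect while
keeping the whole suite to tens of seconds. Composition bookkeeping and
leaflet-size checks use the full 600-lipid scale, where building a single
frame is cheap.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Leaflet assignment by instantaneous midplane can mislabel lipids mid-flip
  in strongly deformed membranes.
- The defect classifier's 10 Å surface window and top-atom visibility rule
  approximate a rendered top-down view; curved or highly rough leaflets
  would need a local reference surface instead of a plane.
- Formal charges at the marker atom are a coarse stand-in for the full
  partial-charge distribution in charge maps.
- H-bond donor typing for lipids relies on the species configuration; exotic
  headgroups need their donor pairs declared explicitly.
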