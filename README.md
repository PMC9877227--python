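# lipidprint

Protein–membrane interaction fingerprinting for molecular-dynamics
trajectories.

When a peripheral membrane protein such as MLKL — the pseudokinase that
permeabilizes the plasma membrane in the last step of necroptosis — binds a
lipid bilayer, it reorganizes the lipids beneath it: anionic inositol lipids
(PIP, PIP₂) and cholesterol are recruited to the binding site while
zwitterionic lipids (DOPC, DOPE) are displaced, and the packing of the
binding leaflet changes. `lipidprint` quantifies this **lipid fingerprint**
from a structure + trajectory pair:

- **Binding and contacts** — binding-leaflet detection, per-residue contact
  frequency (Cα within 12 Å of binding-leaflet phosphates), domain × species
  contact counts, domain COM–membrane distances, insertion depth and the
  deepest inserted residue, Cα RMSD/RMSF after rigid-body superposition.
- **Hydrogen bonds** — geometric criterion (donor–acceptor ≤ 3.2 Å, D–H⋯A
  within 30° of linearity), counted per lipid species over time windows.
- **Surface maps** — cumulative 2D density, relative-height
  (z_f = z − z_o) and formal-charge maps of the membrane plane, plus the
  protein's xy-projection mask.
- **Packing defects** — vdW-disk rasterization of the leaflet surface,
  periodic wrap-aware connected-component labeling of hydrophobic-exposure
  patches, counts/areas per leaflet, and the local defect percentage
  `% = 100 · local defect area / projected protein area`.
- **RDFs and fingerprint** — g(r) from a reference residue's Cα to each
  species' marker atom (P for phospholipids, O3 for cholesterol),
  lipid–lipid RDFs per leaflet, and the local composition under the protein:
  per-species counts, mole fractions, pairwise ratios (e.g. DOPE:PIP₂
  moving from its bulk 5:1), and enrichment indices
  (regional / bulk mole fraction), all with block-averaged standard errors.

A **synthetic trajectory generator** ships with the package: a coarse
bead-model bilayer (five species at 40:32:20:4:4 mol%, 600 lipids per
leaflet at full scale) with lateral Brownian diffusion, a rigid
pseudo-protein that descends and binds, controllable species recruitment,
and plantable hydrogen-bond geometries and packing-defect patches. Every
analysis stage is therefore testable against known ground truth without any
large trajectory downloads.

## Worked example

```python
from lipidprint import SyntheticConfig, detect_binding_leaflet, local_composition, fingerprint_delta
from lipidprint.synth import generate

cfg = SyntheticConfig.test_scale(n_frames=200, binding_frame=20, seed=7,
                                 recruitment_bias={"PIP2": 1.0})
system, truth = generate(cfg)

event = detect_binding_leaflet(system)          # -> leaflet='upper', frame=9
early = local_composition(system, (event.frame, event.frame + 30),
                          cfg.protein_radius, event.leaflet)
late = local_composition(system, (170, 200), cfg.protein_radius, event.leaflet)
print(late.enrichment["PIP2"])                  # 7.007
print(truth["enrichment_PIP2"])                 # 7.314 (generator ground truth)
```

The measured PIP₂ enrichment (regional mole fraction under the protein
divided by the bulk leaflet fraction) recovers the generator's planted
ground truth to ~4% here; values above 1 mean the species is
over-represented at the binding site. `examples/` contains one short script
per capability (building, contacts, hydrogen bonds, maps/defects,
RDF/fingerprint, full pipeline), each printing the numbers it computes and
what they mean.

A thin CLI wraps the generator and the end-to-end pipeline:

```bash
lipidprint generate --scale test --seed 7 --out out/
lipidprint run --config pipeline.yaml
```

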