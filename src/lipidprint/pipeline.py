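"""End-to-end fingerprint analysis pipeline.

One config drives: load (or synthesize) a trajectory, detect the binding
leaflet and frame, then run contacts/depth/RMSD, hydrogen bonds, surface
maps, packing defects, RDFs and the local-composition fingerprint, writing
CSV/JSON artifacts plus a manifest (parameter hash, versions, seed, wall
time) and a summary JSON. Windows are specified relative to the detected
binding frame so early-vs-late comparisons do not hardcode frame numbers.
A stage failure is recorded and later stages that do not depend on it still
run; deterministic outputs are bit-identical for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (domain_com_distance, domain_species_contacts,
                      insertion_depth, residue_contact_frequency, rmsd_series,
                      rmsf)
from .defects import defect_stats
from .fingerprint import fingerprint_delta, local_composition
from .hbonds import count_hbonds_by_species
from .maps import charge_map, density_map, height_map, protein_mask
from .rdf import rdf as rdf_analysis
from .synth import SyntheticConfig, generate, write_outputs
from .system import detect_binding_leaflet, load_system

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ReportBundle"]

log = logging.getLogger("lipidprint")


@dataclass
class PipelineConfig:
    """Validated parameter set for one pipeline run."""

    # input: either file paths...
    structure: str | None = None
    trajectory: str | None = None
    species: str | None = None
    # ...or a synthetic run
    synthetic: dict | None = None
    synthetic_scale: str = "test"  # test | full

    stages: dict[str, bool] = field(default_factory=lambda: {
        "contacts": True, "hbonds": True, "maps": True,
        "defects": True, "rdf": True, "fingerprint": True,
    })
    contact_cutoff: float = 12.0
    hbond_distance: float = 3.2
    hbond_angle: float = 30.0
    bins: int = 100
    cell_size: float = 1.0
    min_defect_area: float = 5.0
    blocks: int = 5
    initial_window_frames: int = 30  # frames after binding
    final_window_frames: int = 30  # frames before trajectory end
    region_radius: float | None = None  # None -> protein-mask region
    rdf_dr: float = 0.5
    outdir: str = "lipidprint_out"
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        has_files = self.structure is not None
        if has_files and self.synthetic is not None:
            errors.append("give either input files or a synthetic config, not both")
        if not has_files and self.synthetic is None:
            errors.append("no input: set structure/trajectory/species or synthetic")
        if has_files:
            for key in ("structure", "species"):
                val = getattr(self, key)
                if val is None:
                    errors.append(f"missing required input path: {key}")
                elif not Path(val).exists():
                    errors.append(f"{key} file not found: {val}")
            if self.trajectory is not None and not Path(self.trajectory).exists():
                errors.append(f"trajectory file not found: {self.trajectory}")
        if self.synthetic_scale not in ("test", "full"):
            errors.append(f"synthetic_scale must be test|full, got {self.synthetic_scale}")
        if self.contact_cutoff <= 0:
            errors.append(f"contact cutoff must be positive, got {self.contact_cutoff}")
        if self.hbond_distance <= 0:
            errors.append(f"hbond distance cutoff must be positive")
        if not 0 < self.hbond_angle <= 90:
            errors.append(f"hbond angle cutoff must be in (0, 90], got {self.hbond_angle}")
        if self.bins < 1 or self.cell_size <= 0:
            errors.append("grid settings invalid (bins >= 1, cell_size > 0)")
        if self.blocks < 2:
            errors.append("block count must be >= 2")
        if self.initial_window_frames < 1 or self.final_window_frames < 1:
            errors.append("window lengths must be >= 1 frame")
        unknown = set(self.stages) - {"contacts", "hbonds", "maps", "defects",
                                      "rdf", "fingerprint"}
        if unknown:
            errors.append(f"unknown stage toggles: {sorted(unknown)}")
        return errors

    def parameter_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location does not identify the run
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + validate a YAML pipeline config; raises ValueError with every
    problem listed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    bad = set(raw) - known
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    errors = [f"unknown config keys: {sorted(bad)}"] if bad else []
    errors += cfg.validate()
    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    return cfg


@dataclass
class ReportBundle:
    outdir: Path
    artifacts: dict[str, Path]
    summary: dict
    manifest: dict


def _write_csv(df: pd.DataFrame, path: Path, artifacts: dict, key: str) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
    artifacts[key] = path


def _write_grid(gm, path: Path, artifacts: dict, key: str) -> None:
    np.savetxt(path, gm.values, fmt="%.6g", delimiter=",")
    meta = {"kind": gm.kind, "bins": gm.bins, "window": list(gm.window),
            "leaflet": gm.leaflet, "species": gm.species,
            "frames": gm.frames_accumulated, "mean_box": list(gm.mean_box)}
    mpath = path.with_suffix(".json")
    mpath.write_text(json.dumps(meta, indent=1))
    artifacts[key] = path


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every enabled stage; see the module docstring for the flow."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {}
    notices: list[str] = []
    summary: dict = {}
    failures: dict[str, str] = {}

    try:
        # -- load or generate ---------------------------------------------
        if config.synthetic is not None:
            overrides = dict(config.synthetic)
            overrides.setdefault("seed", config.seed)
            if config.synthetic_scale == "test":
                scfg = SyntheticConfig.test_scale(**overrides)
            else:
                scfg = SyntheticConfig(**overrides)
            log.info("generating synthetic trajectory: %s-scale, seed %d",
                     config.synthetic_scale, scfg.seed)
            system, truth = generate(scfg)
            write_outputs(system, truth, outdir / "synthetic")
            artifacts["synthetic"] = outdir / "synthetic"
        else:
            log.info("loading %s + %s", config.structure, config.trajectory)
            system = load_system(config.structure, config.trajectory,
                                 config.species)

        # -- binding ------------------------------------------------------
        binding = detect_binding_leaflet(system, cutoff=config.contact_cutoff)
        if binding is None:
            summary["binding"] = None
            notices.append("protein never contacts the membrane; "
                           "binding-dependent stages skipped")
        else:
            summary["binding"] = {"frame": binding.frame, "leaflet": binding.leaflet}
        n = system.n_frames
        if binding is not None:
            w_initial = (binding.frame,
                         min(binding.frame + config.initial_window_frames, n))
            w_final = (max(0, n - config.final_window_frames), n)
            leaflet = binding.leaflet
            summary["windows"] = {"initial": list(w_initial), "final": list(w_final)}

        def stage(name, dependent=True):
            enabled = config.stages.get(name, True)
            if not enabled:
                return False
            if dependent and binding is None:
                notices.append(f"stage {name} skipped: no binding detected")
                return False
            return True

        # -- contacts / depth / rmsd --------------------------------------
        if stage("contacts"):
            log.info("stage contacts")
            try:
                ct = residue_contact_frequency(system, w_final,
                                               config.contact_cutoff, leaflet,
                                               config.blocks)
                _write_csv(ct.per_residue, outdir / "residue_contacts.csv",
                           artifacts, "residue_contacts")
                ds = domain_species_contacts(system, w_final,
                                             config.contact_cutoff, leaflet,
                                             config.blocks)
                _write_csv(ds.per_domain_species,
                           outdir / "domain_species_contacts.csv",
                           artifacts, "domain_species_contacts")
                depth = insertion_depth(system, w_final, leaflet,
                                        config.contact_cutoff)
                _write_csv(
                    depth.depths.rename("depth").rename_axis("resid").reset_index(),
                    outdir / "depth_profile.csv", artifacts, "depth_profile")
                summary["deepest_residue"] = depth.deepest_resid
                com_rows = []
                for dom in system.domains:
                    series = domain_com_distance(system, dom, None, leaflet)
                    com_rows.append(pd.DataFrame(
                        {"frame": np.arange(n), "domain": dom, "distance": series}))
                _write_csv(pd.concat(com_rows, ignore_index=True),
                           outdir / "domain_com_distance.csv",
                           artifacts, "domain_com_distance")
                r = rmsd_series(system)
                _write_csv(pd.DataFrame({"frame": np.arange(n), "rmsd": r}),
                           outdir / "rmsd.csv", artifacts, "rmsd")
                fl = rmsf(system)
                _write_csv(fl.rename("rmsf").rename_axis("resid").reset_index(),
                           outdir / "rmsf.csv", artifacts, "rmsf")
            except Exception as exc:  # stage isolation
                failures["contacts"] = str(exc)
                log.exception("stage contacts failed")

        # -- hydrogen bonds ------------------------------------------------
        if stage("hbonds"):
            log.info("stage hbonds")
            try:
                hb_i = count_hbonds_by_species(system, w_initial,
                                               config.hbond_distance,
                                               config.hbond_angle, config.blocks)
                hb_f = count_hbonds_by_species(system, w_final,
                                               config.hbond_distance,
                                               config.hbond_angle, config.blocks)
                hb_i["window"] = "initial"
                hb_f["window"] = "final"
                _write_csv(pd.concat([hb_i, hb_f], ignore_index=True),
                           outdir / "hbonds_by_species.csv",
                           artifacts, "hbonds_by_species")
                summary["hbond_totals_final"] = dict(
                    zip(hb_f.species, hb_f.total.astype(float)))
            except Exception as exc:
                failures["hbonds"] = str(exc)
                log.exception("stage hbonds failed")

        # -- maps -----------------------------------------------------------
        if stage("maps"):
            log.info("stage maps")
            try:
                for sp in system.registry.names:
                    gm = density_map(system, sp, leaflet, w_final, config.bins)
                    _write_grid(gm, outdir / f"density_{sp}_{leaflet}.csv",
                                artifacts, f"density_{sp}")
                hm = height_map(system, leaflet, w_final, config.bins)
                _write_grid(hm, outdir / "height_map.csv", artifacts, "height_map")
                cm = charge_map(system, leaflet, w_final, config.bins)
                _write_grid(cm, outdir / "charge_map.csv", artifacts, "charge_map")
            except Exception as exc:
                failures["maps"] = str(exc)
                log.exception("stage maps failed")

        # -- defects --------------------------------------------------------
        if stage("defects"):
            log.info("stage defects")
            try:
                ds = defect_stats(system, w_final, ("upper", "lower"),
                                  config.cell_size, config.min_defect_area,
                                  n_blocks=config.blocks, local_leaflet=leaflet)
                _write_csv(ds.per_leaflet, outdir / "defect_stats.csv",
                           artifacts, "defect_stats")
                _write_csv(ds.series, outdir / "defects_series.csv",
                           artifacts, "defects_series")
                if ds.local_pct_bins is not None:
                    _write_csv(ds.local_pct_bins, outdir / "local_percent.csv",
                               artifacts, "local_percent")
                summary["defects"] = ds.per_leaflet.to_dict("records")
            except Exception as exc:
                failures["defects"] = str(exc)
                log.exception("stage defects failed")

        # -- rdf ------------------------------------------------------------
        if stage("rdf"):
            log.info("stage rdf")
            try:
                ref_resid = summary.get("deepest_residue")
                if ref_resid is None:
                    depth = insertion_depth(system, w_final, leaflet,
                                            config.contact_cutoff)
                    ref_resid = depth.deepest_resid
                rows = []
                for sp in system.registry.names:
                    res = rdf_analysis(system, ref_resid, sp, w_final,
                                       dr=config.rdf_dr)
                    rows.append(pd.DataFrame(
                        {"r": res.r, "g": res.g, "species": sp}))
                _write_csv(pd.concat(rows, ignore_index=True),
                           outdir / "rdf.csv", artifacts, "rdf")
            except Exception as exc:
                failures["rdf"] = str(exc)
                log.exception("stage rdf failed")

        # -- fingerprint ----------------------------------------------------
        if stage("fingerprint"):
            log.info("stage fingerprint")
            try:
                if config.region_radius is not None:
                    region = float(config.region_radius)
                else:
                    union = (min(w_initial[0], w_final[0]),
                             max(w_initial[1], w_final[1]))
                    region = protein_mask(system, union, config.cell_size)
                rep_i = local_composition(system, w_initial, region, leaflet,
                                          config.blocks)
                rep_f = local_composition(system, w_final, region, leaflet,
                                          config.blocks)
                fp = pd.DataFrame({
                    "species": rep_f.counts.index,
                    "count_initial": rep_i.counts.to_numpy(),
                    "count_final": rep_f.counts.to_numpy(),
                    "fraction_final": rep_f.fractions.to_numpy(),
                    "enrichment_final": rep_f.enrichment.to_numpy(),
                    "se_final": rep_f.count_se.to_numpy(),
                })
                _write_csv(fp, outdir / "fingerprint.csv", artifacts, "fingerprint")
                delta = fingerprint_delta(rep_i, rep_f)
                _write_csv(delta.rename_axis("species").reset_index(),
                           outdir / "fingerprint_delta.csv",
                           artifacts, "fingerprint_delta")

                def _safe_ratio(rep, a, b):
                    v = rep.ratio(a, b)
                    return None if not np.isfinite(v) else round(float(v), 4)

                summary["fingerprint_ratios"] = {
                    "DOPE:PIP2": {"initial": _safe_ratio(rep_i, "DOPE", "PIP2"),
                                  "final": _safe_ratio(rep_f, "DOPE", "PIP2")},
                    "DOPC:PIP2": {"initial": _safe_ratio(rep_i, "DOPC", "PIP2"),
                                  "final": _safe_ratio(rep_f, "DOPC", "PIP2")},
                } if {"DOPE", "DOPC", "PIP2"} <= set(system.registry.names) else {}
            except Exception as exc:
                failures["fingerprint"] = str(exc)
                log.exception("stage fingerprint failed")

        manifest = {
            "version": __version__,
            "parameter_hash": config.parameter_hash(),
            "config": asdict(config),
            "seed": config.seed,
            "n_frames": n,
            "failures": failures,
            "notices": notices,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         default=str))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                        default=str))
        artifacts["manifest"] = outdir / "manifest.json"
        artifacts["summary"] = outdir / "summary.json"
        return ReportBundle(outdir=outdir, artifacts=artifacts,
                            summary=summary, manifest=manifest)
    finally:
        log.removeHandler(handler)
        handler.close()
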