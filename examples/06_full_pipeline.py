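"""Run the end-to-end pipeline from a single config.

Generates a synthetic trajectory, runs every analysis stage, and prints the
summary: binding event, deepest residue, hydrogen-bond totals, defect stats
and the headline fingerprint ratios. All artifacts (CSVs, maps, manifest)
land in the output directory; rerunning with the same seed reproduces them
bit-identically.
"""

import json
import tempfile
from pathlib import Path

from lipidprint import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as td:
    config = PipelineConfig(
        synthetic={"n_frames": 80, "binding_frame": 15,
                   "recruitment_bias": {"PIP2": 1.0}},
        outdir=str(Path(td) / "run"),
        seed=4,
        initial_window_frames=20,
        final_window_frames=20,
    )
    bundle = run_pipeline(config)
    print("stage artifacts:", ", ".join(sorted(
        p.name for p in bundle.outdir.glob("*.csv"))))
    print("\nsummary:")
    print(json.dumps(bundle.summary, indent=1, default=str))
    print(f"\nparameter hash {bundle.manifest['parameter_hash']} identifies "
          f"this run; identical config + seed => identical CSVs.")
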