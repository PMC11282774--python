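"""End-to-end synthetic run of every analysis stage.

Builds a manifest for two conditions (untreated Ctrl and
freshly-compressed T0), runs all stages on generated fixtures, and
prints the per-condition summary, including the headline delivery
efficiency (planted at 12x).
"""

import json
from pathlib import Path

from mechanoquant import RunManifest, run_pipeline
from mechanoquant.pipeline import ALL_STAGES

outdir = Path("scratch_pipeline_run")
manifest = RunManifest(seed=1, output_dir=outdir, stages=ALL_STAGES,
                       conditions=("Ctrl", "T0"), n_cells=2)
results = run_pipeline(manifest)

for stage, table in results.items():
    print(f"{stage}: {len(table)} rows -> {outdir / (stage + '.csv')}")
summary = json.loads((outdir / "summary.json").read_text())
eff = summary.get("delivery_efficiency_vs_ctrl", {})
if eff:
    print(f"\ndelivery efficiency T0 vs Ctrl: {eff['T0']:.1f}x (planted 12x)")
print("Re-running with the same seed reproduces every output byte for byte.")
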