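"""Run the full config-driven pipeline on synthetic data.

Equivalent to `hemiconn run-all --config <file>`: simulates two runs,
builds all three ROI-set variants, extracts and filters time series,
computes motion QC and Fisher-z connectivity, screens the packaged
behavioral table, and writes the output bundle plus a provenance record.
"""

import tempfile
from pathlib import Path

import pandas as pd

import hemiconn as hc

out = Path(tempfile.mkdtemp(prefix="hemiconn_demo_"))
config = hc.RunConfig(
    mode="synthetic",
    out_dir=str(out),
    seed=7,
    n_runs=2,
    signal={"n_volumes": 200},  # shorter demo runs
    variants=["bilateral", "left", "right"],
)
provenance = hc.run_pipeline(config)

summary = pd.read_csv(out / "network_summary.tsv", sep="\t")
print(summary.to_string(index=False))
print(f"\n{len(provenance['outputs'])} files written to {out}")
print("Each row is one subject x ROI-set variant; 'diff' (pooled within-"
      "network minus between-network mean Fisher z) stays positive in every "
      "variant because the planted network structure is hemispherically "
      "symmetric — the same comparison the analysis makes on real data.")
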