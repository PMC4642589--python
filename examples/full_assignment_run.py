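"""End-to-end synthetic assignment run on a small disordered chain.

Generates a 20-residue IDP-like shift table, simulates the sparse 6D
experiment at the published 800 MHz evolution times, processes it into
HNCO-anchored cross-sections, decodes the predecessor frequencies and
chains the anchors sequentially, then scores the links against the
generating truth.
"""

import json
import tempfile

from nusproj import run_pipeline
from nusproj.config import ChainConfig, RunConfig, ScheduleConfig

config = RunConfig.preset(
    "800MHz-6D",
    chain=ChainConfig(n_residues=20, seed=5, proline_at=[11],
                      exchange_broadened_prefix=1),
    schedule=ScheduleConfig(n_points=1500, seed=2),
    output_dir=tempfile.mkdtemp(prefix="nusproj_demo_"))

summary = run_pipeline(config)
print(json.dumps({"counts": summary["counts"],
                  "recovery": summary["recovery"]}, indent=2))
print(f"\nartifacts written to {config.output_dir}")
print("\nResidue 11 is a proline (no amide anchor) and residue 1 is exchange-")
print("broadened, so the chain breaks there; every remaining sequential link")
print("should be recovered (fraction_correct = 1.0) with no false links.")
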