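"""Run the whole pipeline end to end and print the run summary.

Equivalent to `scnkit run-all --out-dir <dir>` with a small configuration:
simulate -> build networks -> threshold sweep + AUC -> comparisons,
moderation models and trajectories, with a checksummed manifest.
"""

import tempfile
import warnings
from pathlib import Path

from scnkit import CohortConfig
from scnkit.pipeline import PipelineOptions, run_pipeline, summarize_run
from scnkit.types import ThresholdGrid

config = CohortConfig(n_roi=20, n_modules=2, n_timepoints_ts=80, seed=11)
options = PipelineOptions(grid=ThresholdGrid(0.10, 0.40, 0.10), n_null=10)

out = Path(tempfile.mkdtemp()) / "run"
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_pipeline(config, out, options)

print(f"{len(manifest['files'])} files written to {out}")
print(f"config hash {manifest['config_hash']}, seed {manifest['seed']}\n")
print(summarize_run(out))
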