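"""Run the whole mining analysis from one config.

Synthetic mode simulates the study inputs, then runs
mine -> cluster -> specificity -> rank, writing intermediate artifacts
and a machine- plus human-readable report. Reruns with the same config
and seed are byte-identical.
"""

import tempfile
from pathlib import Path

from clademiner.pipeline import PipelineConfig, run_pipeline

outdir = Path(tempfile.mkdtemp()) / "pipeline_run"
config = PipelineConfig(outdir=str(outdir), seed=1, n_shuffles=100)
report = run_pipeline(config)

print(report.to_text())
print("artifacts written:")
for path in sorted(outdir.rglob("*")):
    if path.is_file():
        print(f"  {path.relative_to(outdir)}")
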