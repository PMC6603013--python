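"""The end-to-end demo pipeline.

With a fully-defaulted configuration the pipeline simulates the
methylbenzene family and a 12-band concentration series, then writes
second-derivative spectra, difference spectra, correlation maps with
autopeaks, peak assignments and the substituent reports, all hashed into a
reproducible manifest.
"""

import json
from pathlib import Path

from nirassign import RunConfig, run_assignment_pipeline

outdir = Path("scratch/pipeline_demo")
manifest = run_assignment_pipeline(RunConfig(outdir=str(outdir), seed=0))

print("artifact classes:", ", ".join(sorted(manifest["artifacts"])))
reports = json.loads((outdir / "reports" / "reports.json").read_text())
print("linearity r^2:", reports["linearity"]["r_squared"])
print("shift ordering:", " < ".join(reports["shift"]["ordering"]))
print("width ordering:", " > ".join(reports["width"]["ordering"]))
print("\nRe-running with the same seed reproduces every output byte for byte;"
      " see manifest.json for the SHA-256 of each artifact.")
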