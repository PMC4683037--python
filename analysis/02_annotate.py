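#!/usr/bin/env python
"""Length-filter the libraries to 18-30 nt, map reads perfectly to the
genome on both strands, and classify them into the non-coding categories
(known miRNA, rRNA, tRNA, snoRNA, snRNA, others).

Writes results/analysis_run/annotate/ and prints the per-library category
totals."""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config  # noqa: E402

from seedmir.pipeline import run_pipeline  # noqa: E402

cfg = analysis_config()
run_pipeline(cfg, stages=("annotate",), resume=True)
summary = pd.read_csv(Path(cfg.outdir) / "annotate/summary.tsv", sep="\t",
                      na_values=["NA"])
pivot = summary.pivot(index="row", columns="library", values="reads")
print("reads per category and library:")
print(pivot.to_string())
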