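#!/usr/bin/env python
"""Compute TPM (reads per million clean reads) for the catalog, max-normalise
each profile, and flag miRNAs whose normalised value drops below 0.5 in some
library (>2-fold change) as differentially expressed.

Writes results/analysis_run/express/ and prints the differential tally."""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config  # noqa: E402

from seedmir.pipeline import run_pipeline  # noqa: E402

cfg = analysis_config()
run_pipeline(cfg, stages=("express",), resume=True)
calls = pd.read_csv(Path(cfg.outdir) / "express/differential.tsv", sep="\t")
n_diff = int(calls["is_differential"].sum())
print(f"{n_diff} of {len(calls)} expressed miRNAs called differential")
print("peak library of differential miRNAs:")
print(calls[calls["is_differential"]]["max_library"].value_counts().to_string())
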