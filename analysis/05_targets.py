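#!/usr/bin/env python
"""Scan the transcriptome with the six-rule duplex filter (plus a stricter
preset), confirm sites against degradome tags with the binomial slice test,
and correlate miRNA and target expression.

Writes results/analysis_run/targets/ and prints site and overlap counts."""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config  # noqa: E402

from seedmir.pipeline import run_pipeline  # noqa: E402

cfg = analysis_config()
run_pipeline(cfg, stages=("targets",), resume=True)
out = Path(cfg.outdir) / "targets"
sites = pd.read_csv(out / "sites.tsv", sep="\t")
venn = pd.read_csv(out / "venn.tsv", sep="\t")
pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
print(f"{len(sites)} sites pass all six rules; "
      f"{int(sites['degradome_confirmed'].sum())} degradome-confirmed (p<0.05)")
print("method overlap (miRNA-transcript pairs):")
print(venn.to_string(index=False))
if len(pairs):
    print(f"{int(pairs['inverse_pair'].sum())} of {len(pairs)} expressed "
          "pairs are inversely correlated (folds>2, r<-0.5)")
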