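#!/usr/bin/env python
"""Fold 150-nt-flanked windows around unannotated mapped reads, trim each to
its stem-loop, and apply the four novel-miRNA criteria (mature 20-24 nt,
fold-back precursor >=45 nt, >5 reads in some library, MFEI > 0.85 or an
observed miRNA*).

Writes results/analysis_run/discover/ and prints the recovered catalog."""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config  # noqa: E402

from seedmir.pipeline import run_pipeline  # noqa: E402

cfg = analysis_config()
manifest = run_pipeline(cfg, stages=("discover",), resume=True)
catalog = pd.read_csv(Path(cfg.outdir) / "discover/catalog.tsv", sep="\t")
n_mirnas = catalog["mirna"].nunique()
print(f"{n_mirnas} novel miRNAs from {len(catalog)} precursors")
print(f"MFEI range {catalog['mfei'].min():.2f}-{catalog['mfei'].max():.2f}, "
      f"precursor lengths {catalog['precursor_length'].min()}-"
      f"{catalog['precursor_length'].max()} nt")
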