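#!/usr/bin/env python
"""Emit the final report tables: the classification summary in the published
table's shape (reads/unique columns with footnote-convention percentages),
the read size distribution, and the catalog first-base composition.

Writes results/analysis_run/report/."""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config  # noqa: E402

from seedmir.pipeline import run_pipeline  # noqa: E402

cfg = analysis_config()
run_pipeline(cfg, stages=("report",), resume=True)
out = Path(cfg.outdir) / "report"
size = pd.read_csv(out / "size_distribution.tsv", sep="\t")
peaks = size.sort_values("fraction", ascending=False).groupby("library").head(2)
print("dominant read lengths per library:")
print(peaks.sort_values(["library", "length"]).to_string(index=False))
fb = pd.read_csv(out / "first_base.tsv", sep="\t")
if len(fb):
    print("\ncatalog first-base composition:")
    print(fb.to_string(index=False))
print(f"\nfull tables under {out}/")
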