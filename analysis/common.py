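"""Shared run configuration for the numbered analysis drivers.

All drivers operate on one run directory (results/analysis_run) at the
standard study conditions: three libraries (0/12/24 HAI), 1e5 reads each,
20 planted novel hairpins and 5 decoys per violated-criterion class.
"""

from seedmir.pipeline import PipelineConfig


def analysis_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(outdir="results/analysis_run", seed=seed)
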