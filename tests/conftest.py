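"""Shared fixtures: the standard synthetic fixture (full-scale criteria
recovery) and a small bundle for fast structural tests."""

import numpy as np
import pytest

from seedmir.simulate import (SimulationConfig, generate_reference,
                              simulate_degradome, simulate_libraries,
                              simulate_transcriptome, transcript_expression)


@pytest.fixture(scope="session")
def std_cfg():
    """The standard study-condition fixture: 20 pass hairpins, 5 decoys per
    criterion class, 1e5 reads per library, seed 1."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def std_ref(std_cfg):
    return generate_reference(std_cfg)


@pytest.fixture(scope="session")
def std_table(std_ref, std_cfg):
    return simulate_libraries(std_ref, std_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        genome_length=30_000, n_known_mirnas=4, n_novel_mirnas=6,
        n_decoy_hairpins=2, reads_per_library=20_000, n_transcripts=6,
        n_noise_intergenic=60, n_noise_fragments=80, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """Reference + libraries + transcriptome + degradome, small scale."""
    ref = generate_reference(small_cfg)
    table = simulate_libraries(ref, small_cfg)
    simulate_transcriptome(ref, small_cfg)
    tx_expr = transcript_expression(ref, small_cfg)
    degradome = simulate_degradome(ref, small_cfg)
    return {"ref": ref, "table": table, "tx_expr": tx_expr,
            "degradome": degradome, "cfg": small_cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
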