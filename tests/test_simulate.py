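"""Synthetic-data generator: determinism, conservation, constructive truth
of planted hairpins, abundance calibration, and degradome tag placement."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from seedmir.simulate import (SimulationConfig, _draw_profile,
                              generate_reference, intended_rule_verdicts,
                              simulate_degradome, simulate_libraries,
                              simulate_transcriptome)
from seedmir.io import revcomp


TINY = dict(genome_length=22_000, n_known_mirnas=2, n_novel_mirnas=4,
            n_decoy_hairpins=1, reads_per_library=5_000,
            n_noise_intergenic=30, n_noise_fragments=40, n_transcripts=4)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        cfgs = [SimulationConfig(seed=5, **TINY) for _ in range(2)]
        refs = [generate_reference(c) for c in cfgs]
        assert refs[0].genome.residues == refs[1].genome.residues
        assert [m.mature for m in refs[0].registry.planted_mirnas] == \
               [m.mature for m in refs[1].registry.planted_mirnas]
        tables = [simulate_libraries(r, c) for r, c in zip(refs, cfgs)]
        assert {k: list(v) for k, v in tables[0].counts.items()} == \
               {k: list(v) for k, v in tables[1].counts.items()}
        txs = [simulate_transcriptome(r, c) for r, c in zip(refs, cfgs)]
        assert [t.residues for t in txs[0]] == [t.residues for t in txs[1]]
        degs = [simulate_degradome(r, c) for r, c in zip(refs, cfgs)]
        assert degs[0].equals(degs[1])

    def test_no_novel_requested_means_none_planted(self):
        cfg = SimulationConfig(seed=2, **{**TINY, "n_novel_mirnas": 0,
                                          "n_decoy_hairpins": 0})
        ref = generate_reference(cfg)
        cats = {m.category for m in ref.registry.planted_mirnas}
        assert "novel" not in cats and "decoy" not in cats


class TestConstructiveTruth:
    def test_genome_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            generate_reference(SimulationConfig(seed=1, **{**TINY,
                                                           "genome_length": 3_000}))

    def test_decoys_annotated_with_one_violated_criterion(self, small_bundle):
        reg = small_bundle["ref"].registry
        decoys = [m for m in reg.planted_mirnas if m.category == "decoy"]
        assert decoys and all(m.decoy_class is not None for m in decoys)
        assert all(not m.intended_pass for m in decoys)

    def test_precursor_sequences_are_foldback_palindromes(self, small_bundle):
        ref = small_bundle["ref"]
        g = ref.genome.residues
        for m in ref.registry.planted_mirnas:
            if not m.intended_pass:
                continue
            prec = g[m.precursor.start:m.precursor.end]
            assert prec.startswith(m.mature)
            # the 3' arm carries the reverse complement of the mature
            assert revcomp(m.mature) in prec[len(m.mature):]


class TestLibraries:
    def test_exact_read_conservation(self, std_table, std_cfg):
        totals = std_table.total_counts()
        assert (totals == std_cfg.reads_per_library).all()

    def test_realized_tpm_within_three_standard_errors(self, std_ref, std_table, std_cfg):
        """Multinomial sampling keeps realized counts near intent: every draw
        within 5 SE, and at most 1% beyond 3 SE (the expected tail share for
        this many draws is ~0.3%)."""
        reg = std_ref.registry
        n = std_cfg.reads_per_library
        checked, beyond3 = 0, 0
        for name, tpm in reg.planted_tpm.items():
            mature = reg.by_name(name).mature
            counts = std_table.counts.get(mature)
            assert counts is not None, f"{name} drew zero reads everywhere"
            for j, intended in enumerate(tpm):
                p = intended / 1e6
                se = np.sqrt(n * p * (1 - p))
                dev = abs(counts[j] - n * p)
                assert dev <= 5 * se + 1
                beyond3 += dev > 3 * se + 1
                checked += 1
        assert checked >= 100
        assert beyond3 <= max(1, 0.01 * checked)

    def test_full_noise_leaves_precursors_untouched(self):
        cfg = SimulationConfig(seed=3, noise_fraction=1.0, **TINY)
        ref = generate_reference(cfg)
        table = simulate_libraries(ref, cfg)
        precs = [(m.precursor.start, m.precursor.end)
                 for m in ref.registry.planted_mirnas]
        g = ref.genome.residues
        for seq in table.counts:
            for s, e in precs:
                assert seq not in g[s:e] and revcomp(seq) not in g[s:e]

    def test_nondifferential_profiles_stay_flat(self):
        cfg = SimulationConfig(seed=4, differential_fraction=0.0, **TINY)
        rng = np.random.default_rng(0)
        for _ in range(200):
            prof = _draw_profile(rng, cfg, differential=False)
            assert prof.max() / prof.min() <= 1.3
        prof = _draw_profile(rng, cfg, differential=True)
        assert prof.max() / prof.min() > 2.0


class TestTranscriptome:
    def test_perfect_pattern_is_exact_reverse_complement(self, small_bundle):
        ref = small_bundle["ref"]
        site = next(s for s in ref.registry.planted_sites if s.pattern == "perfect")
        tx = next(t for t in ref.transcripts if t.id == site.transcript)
        mature = ref.registry.by_name(site.mirna).mature
        assert tx.residues[site.span[0]:site.span[1]] == revcomp(mature)

    def test_cleavage_rule_pattern_intends_rule4_failure(self):
        verdicts = intended_rule_verdicts("A" * 21, [("mm", 10)])
        assert not verdicts["cleavage_match"]
        assert not all(verdicts.values())

    def test_edit_outside_mirna_raises(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, seed=9,
                                  site_rule_profile=("mm@40",))
        ref = generate_reference(cfg)
        with pytest.raises(ValueError):
            simulate_transcriptome(ref, cfg)


class TestDegradome:
    def test_full_signal_concentrates_at_slice(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, degradome_signal_fraction=1.0)
        ref = generate_reference(cfg)
        simulate_libraries(ref, cfg)
        simulate_transcriptome(ref, cfg)
        tags = simulate_degradome(ref, cfg)
        slices = {(s.transcript, s.cleavage_position)
                  for s in ref.registry.planted_sites if s.expect_pass}
        site_tx = {t for t, _ in slices}
        on_site = tags[tags["transcript"].isin(site_tx)]
        assert set(zip(on_site["transcript"], on_site["position"])) <= slices

    def test_zero_signal_tags_are_uniform(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, degradome_signal_fraction=0.0,
                                  degradome_tags_per_transcript=2_500)
        ref = generate_reference(cfg)
        simulate_libraries(ref, cfg)
        simulate_transcriptome(ref, cfg)
        tags = simulate_degradome(ref, cfg, seed=123)
        tx = ref.transcripts[0]
        sub = tags[tags["transcript"] == tx.id]
        # chi-square goodness of fit against uniform over 20 position bins
        L = len(tx.residues)
        bins = np.zeros(20)
        for _, r in sub.iterrows():
            bins[min(19, int(r["position"] * 20 / L))] += r["count"]
        p = stats.chisquare(bins).pvalue
        assert p > 0.01

    def test_half_signal_within_binomial_interval(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, degradome_signal_fraction=0.5,
                                  degradome_tags_per_transcript=200)
        ref = generate_reference(cfg)
        simulate_libraries(ref, cfg)
        simulate_transcriptome(ref, cfg)
        tags = simulate_degradome(ref, cfg, seed=7)
        site = next(s for s in ref.registry.planted_sites if s.expect_pass)
        at = tags[(tags["transcript"] == site.transcript)
                  & (tags["position"] == site.cleavage_position)]["count"].sum()
        lo, hi = stats.binom.interval(0.99, 200, 0.5)
        # uniform background can add a few tags at the slice position
        assert lo <= at <= hi + 3
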