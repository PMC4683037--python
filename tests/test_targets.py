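"""Duplex alignment states, the six target rules, hybridisation energy,
transcriptome scanning, degradome confirmation and method overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seedmir import targets as tg
from seedmir.io import SequenceRecord, revcomp

MIRNA = "TGAAGCTGCCAGCATGATCTA"  # 21 nt


def _site_for_states(mirna, states, rng=None):
    """Construct a transcript-sense site realising the given pairing states."""
    L = len(mirna)
    site = [None] * L
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, st in enumerate(states):
        m = mirna[i]
        j = L - 1 - i
        if st == "match":
            site[j] = comp[m]
        elif st == "GU":
            assert m in "GT", "G:U requires G or U on the miRNA side"
            site[j] = "T" if m == "G" else "G"
        else:
            site[j] = {"A": "A", "C": "C", "G": "A", "T": "C"}[m]
    return "".join(site)


class TestAlignDuplex:
    def test_perfect_reverse_complement(self):
        a = tg.align_duplex(MIRNA, revcomp(MIRNA))
        assert set(a.states) == {"match"} and a.mismatch_score == 0

    def test_single_gu_half_mismatch(self):
        states = ["match"] * 21
        states[4] = "GU"
        a = tg.align_duplex(MIRNA, _site_for_states(MIRNA, states))
        assert a.states == states and a.mismatch_score == 0.5

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            tg.align_duplex("ACGT", "ACG")

    def test_states_match_manual_checker(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(100):
            mir = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            site = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            a = tg.align_duplex(mir, site)
            for i in range(21):
                m, s = mir[i], site[21 - 1 - i]
                if s == comp[m]:
                    expect = "match"
                elif (m, s) in (("G", "T"), ("T", "G")):
                    expect = "GU"
                else:
                    expect = "mismatch"
                assert a.states[i] == expect


class TestScoreRules:
    def _verdicts(self, states):
        site = _site_for_states(MIRNA, states)
        return tg.score_rules(tg.align_duplex(MIRNA, site))

    def test_perfect_duplex_passes_all(self):
        v = self._verdicts(["match"] * 21)
        assert all(v.values())

    def test_mismatch_at_ten_fails_cleavage_rule(self):
        states = ["match"] * 21
        states[9] = "mismatch"
        v = self._verdicts(states)
        assert not v["cleavage_match"] and not all(v.values())

    def test_five_scattered_mismatches_fail_total(self):
        states = ["match"] * 21
        for i in (0, 3, 6, 13, 16):
            states[i] = "mismatch"
        v = self._verdicts(states)
        assert not v["total_mismatch"]

    def test_gu_counts_half_toward_totals(self):
        # wobbles only at miRNA positions carrying G or U, spaced so the
        # adjacency rules stay silent: 7 wobbles = 3.5 mismatches
        states = ["match"] * 21
        for i in (0, 4, 6, 11, 14, 17, 19):
            states[i] = "GU"
        v = self._verdicts(states)
        assert v["total_mismatch"]  # 3.5 <= 4
        states[15] = "GU"  # 8 wobbles = 4.0, still within the bound
        assert self._verdicts(states)["total_mismatch"]

    def test_three_adjacent_nonmatches_fail_run_rule(self):
        states = ["match"] * 21
        for i in (13, 14, 15):
            states[i] = "mismatch"
        v = self._verdicts(states)
        assert not v["adjacent_run"]

    def test_adjacent_in_seed_fails_rule3_even_with_gu(self):
        states = ["match"] * 21
        states[4], states[5] = "GU", "mismatch"
        mir = MIRNA[:4] + "G" + MIRNA[5:]
        site = _site_for_states(mir, states)
        v = tg.score_rules(tg.align_duplex(mir, site))
        assert not v["seed_adjacent"]


class TestDuplexEnergy:
    def test_perfect_ratio_one(self):
        a = tg.align_duplex(MIRNA, revcomp(MIRNA))
        assert a.energy_ratio == pytest.approx(1.0)
        assert a.duplex_energy < 0

    def test_all_mismatch_ratio_zero(self):
        site = _site_for_states(MIRNA, ["mismatch"] * 21)
        a = tg.align_duplex(MIRNA, site)
        assert a.duplex_energy == 0.0 and a.energy_ratio == 0.0
        assert not tg.score_rules(a)["energy_ratio"]

    def test_energy_degrades_monotonically(self, rng):
        states = ["match"] * 21
        last = abs(tg.align_duplex(MIRNA, _site_for_states(MIRNA, states)).duplex_energy)
        order = list(rng.permutation(21))
        for i in order:
            states[i] = "mismatch"
            e = abs(tg.align_duplex(MIRNA, _site_for_states(MIRNA, states)).duplex_energy)
            assert e <= last + 1e-9
            last = e


class TestScan:
    def test_planted_perfect_site_found(self, rng):
        mir = SequenceRecord("m", MIRNA)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        tx = SequenceRecord("t", bg[:90] + revcomp(MIRNA) + bg[90:])
        sites = tg.scan_transcripts([mir], [tx])
        spans = [s.span for s in sites]
        assert (90, 111) in spans
        site = next(s for s in sites if s.span == (90, 111))
        assert site.cleavage_position == 90 + 21 - 10

    def test_toy_transcript_equals_window_brute_force(self, rng):
        tx = SequenceRecord("t", "".join("ACGT"[i] for i in rng.integers(0, 4, 60)))
        for _ in range(5):
            mir = SequenceRecord("m", "".join("ACGT"[i] for i in rng.integers(0, 4, 21)))
            fast = {s.span for s in tg.scan_transcripts([mir], [tx])}
            brute = set()
            for w in range(60 - 21 + 1):
                a = tg.align_duplex(mir.residues, tx.residues[w:w + 21])
                if all(tg.score_rules(a).values()):
                    brute.add((w, w + 21))
            assert fast == brute

    def test_concatenation_order_invariance(self, rng):
        txs = [SequenceRecord(f"t{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 80)))
               for i in range(4)]
        mir = SequenceRecord("m", MIRNA)
        txs[1] = SequenceRecord("t1", txs[1].residues[:30] + revcomp(MIRNA)
                                + txs[1].residues[30:])
        a = {(s.transcript_id, s.span) for s in tg.scan_transcripts([mir], txs)}
        b = {(s.transcript_id, s.span) for s in tg.scan_transcripts([mir], txs[::-1])}
        assert a == b

    def test_relaxing_thresholds_never_shrinks_passing_set(self, rng):
        txs = [SequenceRecord("t", "".join("ACGT"[i] for i in rng.integers(0, 4, 400)))]
        mir = SequenceRecord("m", MIRNA)
        txs[0] = SequenceRecord("t", txs[0].residues[:50] + revcomp(MIRNA)
                                + txs[0].residues[50:])
        strict = {s.span for s in tg.scan_transcripts(
            [mir], txs, max_total_mismatch=2.0, min_energy_ratio=0.9)}
        loose = {s.span for s in tg.scan_transcripts(
            [mir], txs, max_total_mismatch=4.0, min_energy_ratio=0.75)}
        assert strict <= loose

    def test_planted_site_verdicts_equal_registry_intent(self, small_bundle):
        ref = small_bundle["ref"]
        reg = ref.registry
        for site in reg.planted_sites:
            mature = reg.by_name(site.mirna).mature
            tx = next(t for t in ref.transcripts if t.id == site.transcript)
            window = tx.residues[site.span[0]:site.span[1]]
            a = tg.align_duplex(mature, window)
            assert tg.score_rules(a) == site.intended_verdicts, site.pattern


def _dummy_site(cleavage=250, tx="tx"):
    a = tg.align_duplex(MIRNA, revcomp(MIRNA))
    return tg.TargetSite("m", tx, (cleavage - 11, cleavage + 10), a,
                         tg.score_rules(a), cleavage)


class TestDegradomeConfirm:
    def test_extreme_signal_confirmed(self):
        tags = pd.DataFrame({"transcript": ["tx"], "position": [250],
                             "count": [100]})
        ev = tg.degradome_confirm(_dummy_site(), tags, 500)
        assert ev.confirmed and ev.p_value < 1e-10

    def test_uniform_tags_off_slice_unconfirmed(self):
        tags = pd.DataFrame({"transcript": "tx",
                             "position": [i for i in range(0, 500, 10) if i not in (249, 250)],
                             "count": 1})
        ev = tg.degradome_confirm(_dummy_site(), tags, 500)
        assert not ev.confirmed and ev.p_value == pytest.approx(1.0)

    def test_zero_tags_undefined(self):
        tags = pd.DataFrame({"transcript": [], "position": [], "count": []})
        ev = tg.degradome_confirm(_dummy_site(), tags, 500)
        assert ev.p_value is None and not ev.confirmed

    def test_slice_covers_both_cleavage_positions(self):
        tags = pd.DataFrame({"transcript": ["tx", "tx"],
                             "position": [249, 250], "count": [40, 40]})
        ev = tg.degradome_confirm(_dummy_site(), tags, 500)
        assert ev.tags_at_slice == 80 and ev.confirmed


class TestOverlap:
    def test_identical_sets(self):
        s = {("m1", "t1"), ("m2", "t2")}
        counts = tg.overlap_methods({"a": set(s), "b": set(s)})
        assert counts == {"a&b": 2}

    def test_disjoint_sets(self):
        counts = tg.overlap_methods({"a": {("m", "t")}, "b": {("m", "u")}})
        assert counts == {"a": 1, "b": 1}

    def test_random_sets_equal_brute_force(self, rng):
        pairs = [(f"m{i}", f"t{j}") for i in range(6) for j in range(6)]
        sets = {name: {pairs[k] for k in rng.choice(len(pairs), 12, replace=False)}
                for name in ("a", "b", "c")}
        counts = tg.overlap_methods(sets)
        assert sum(counts.values()) == len(sets["a"] | sets["b"] | sets["c"])
        for combo_len in (1, 2, 3):
            for members in itertools.combinations("abc", combo_len):
                exact = set.intersection(*[sets[m] for m in members])
                for other in set("abc") - set(members):
                    exact -= sets[other]
                key = "&".join(members)
                assert counts.get(key, 0) == len(exact)
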