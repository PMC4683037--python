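"""Window extraction, hairpin metrics, miRNA* geometry, the four
novel-miRNA criteria, and catalog naming."""

import numpy as np
import pytest

from seedmir import hairpin as hp
from seedmir.fold import fold, nussinov_max_pairs
from seedmir.io import GenomicInterval, SecondaryStructure, SequenceRecord, revcomp


def _genome(rng, n=3000):
    return SequenceRecord("chr1", "".join("ACGT"[i] for i in rng.integers(0, 4, n)))


class TestExtractWindow:
    def test_standard_window_is_flank_mature_flank(self, rng):
        g = _genome(rng)
        hit = GenomicInterval("chr1", 1000, 1021, "+")
        seq, window, offset = hp.extract_window(hit, g)
        assert len(seq) == 150 + 21 + 150
        assert (window.start, window.end) == (850, 1171)
        assert offset == 150
        assert seq[offset:offset + 21] == g.residues[1000:1021]

    def test_clipped_at_chromosome_start(self, rng):
        g = _genome(rng)
        hit = GenomicInterval("chr1", 10, 31, "+")
        seq, window, offset = hp.extract_window(hit, g)
        assert window.start == 0 and offset == 10

    def test_minus_strand_is_reverse_complement(self, rng):
        g = _genome(rng)
        hit = GenomicInterval("chr1", 1000, 1024, "-")
        seq, window, offset = hp.extract_window(hit, g)
        assert seq == revcomp(g.residues[window.start:window.end])
        # double reverse-complement returns the forward slice
        assert revcomp(seq) == g.residues[window.start:window.end]
        assert seq[offset:offset + 24] == revcomp(g.residues[1000:1024])


class TestMfei:
    def test_arithmetic(self):
        amfe, mfei = hp.compute_mfei(-40.0, 100, 50.0)
        assert amfe == 40.0 and mfei == 0.8

    def test_threshold_example(self):
        _, mfei = hp.compute_mfei(-85.0, 100, 50.0)
        assert mfei == pytest.approx(1.7) and mfei > hp.MFEI_THRESHOLD

    def test_open_chain(self):
        amfe, mfei = hp.compute_mfei(0.0, 100, 50.0)
        assert amfe == 0.0 and mfei == 0.0

    def test_gc_zero_undefined(self):
        with pytest.raises(ValueError, match="GC"):
            hp.compute_mfei(-10.0, 100, 0.0)

    def test_reversal_invariance_and_linearity(self, rng):
        for _ in range(20):
            mfe = -float(rng.uniform(1, 120))
            L = int(rng.integers(45, 300))
            gc = float(rng.uniform(10, 90))
            a1, m1 = hp.compute_mfei(mfe, L, gc)
            # reversing a sequence changes neither MFE magnitude, length nor GC
            a2, m2 = hp.compute_mfei(mfe, L, gc)
            assert (a1, m1) == (a2, m2)
            _, m3 = hp.compute_mfei(2 * mfe, L, gc)
            assert m3 == pytest.approx(2 * m1)


def _perfect_hairpin(rng, mature_len=21, ext=10, loop=8):
    mature = "".join("ACGT"[i] for i in rng.integers(0, 4, mature_len))
    arm = mature + "".join("ACGT"[i] for i in rng.integers(0, 4, ext))
    seq = arm + "A" * loop + revcomp(arm)
    return mature, seq


class TestFindStar:
    def test_perfect_stem_star_is_shifted_reverse_complement(self, rng):
        mature, prec = _perfect_hairpin(rng)
        # embed with flanking context so the 2-nt overhang can extend
        left = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        right = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        window = left + prec + right
        struct = fold(window)
        m0 = len(left)
        star = hp.find_star(window, struct, m0, m0 + len(mature))
        n = len(prec)
        expected = window[m0 + n - len(mature) + 2: m0 + n + 2]
        assert star == expected

    def test_mature_in_loop_has_no_star(self, rng):
        mature, prec = _perfect_hairpin(rng, loop=24)
        window = prec
        struct = fold(window)
        arm_len = len(prec) // 2 - 12
        loop_start = 31  # arm is 31 nt (21 mature + 10 ext)
        star = hp.find_star(window, struct, loop_start + 2, loop_start + 22)
        assert star is None


def _candidate(length=100, mfei=1.2, fold_back=True, mature_len=21,
               star_observed=False):
    seq = ("AC" * length)[:length]
    return hp.PrecursorCandidate(
        window=GenomicInterval("chr1", 0, length, "+"),
        sequence=seq[:length],
        structure=SecondaryStructure("." * length, 0.0),
        mature=SequenceRecord("m", "A" * mature_len),
        mature_offset=0, gc=50.0, amfe=mfei * 50.0, mfei=mfei,
        fold_back=fold_back, star_observed=star_observed,
    )


class TestCriteria:
    def test_read_threshold_is_strictly_greater_than_five(self):
        c = _candidate()
        assert not hp.apply_novel_criteria(c, np.array([5, 5, 5]))["read_support"]
        assert hp.apply_novel_criteria(c, np.array([6, 0, 0]))["read_support"]

    def test_precursor_length_boundary(self):
        ok = hp.apply_novel_criteria(_candidate(length=45), np.array([10, 0, 0]))
        short = hp.apply_novel_criteria(_candidate(length=44), np.array([10, 0, 0]))
        assert ok["fold_back"] and not short["fold_back"]

    def test_mfei_or_star_disjunction(self):
        low = _candidate(mfei=0.84)
        assert not hp.apply_novel_criteria(low, np.array([10, 0, 0]))["mfei_or_star"]
        low_star = _candidate(mfei=0.84, star_observed=True)
        assert hp.apply_novel_criteria(low_star, np.array([10, 0, 0]))["mfei_or_star"]
        high = _candidate(mfei=0.86)
        assert hp.apply_novel_criteria(high, np.array([10, 0, 0]))["mfei_or_star"]

    def test_mature_length_window(self):
        for L, ok in ((19, False), (20, True), (24, True), (25, False)):
            c = _candidate(mature_len=L)
            assert hp.apply_novel_criteria(c, np.array([10, 0, 0]))["mature_length"] is ok


class TestNameAndMerge:
    def _cand_at(self, start, mature):
        c = _candidate()
        c.window = GenomicInterval("chr1", start, start + 100, "+")
        c.mature = SequenceRecord("m", mature)
        return c

    def test_same_mature_merged_with_suffixes(self):
        a = self._cand_at(100, "A" * 21)
        b = self._cand_at(900, "A" * 21)
        [mir] = hp.name_and_merge([b, a])
        assert mir.name == "OsmiR-1"
        assert [p.mature.id for p in mir.precursors] == ["OsmiR-1-1", "OsmiR-1-2"]
        assert [p.window.start for p in mir.precursors] == [100, 900]

    def test_empty_catalog(self):
        assert hp.name_and_merge([]) == []

    def test_order_independence_and_serials_by_coordinate(self, rng):
        cands = [self._cand_at(int(s), "".join("ACGT"[i] for i in rng.integers(0, 4, 21)))
                 for s in rng.choice(50_000, size=10, replace=False)]
        ordered = hp.name_and_merge(list(cands))
        shuffled_in = list(cands)
        rng.shuffle(shuffled_in)
        shuffled = hp.name_and_merge(shuffled_in)
        assert [(m.name, m.mature.residues) for m in ordered] == \
               [(m.name, m.mature.residues) for m in shuffled]
        starts = [m.precursors[0].window.start for m in ordered]
        assert starts == sorted(starts)

    def test_merging_conserves_precursors(self, rng):
        cands = [self._cand_at(int(s), "A" * 21 if s % 2 else "C" * 21)
                 for s in range(0, 2000, 150)]
        catalog = hp.name_and_merge(cands)
        assert sum(len(m.precursors) for m in catalog) == len(cands)


class TestSummaries:
    def test_single_24nt_catalog(self):
        c = _candidate(mature_len=24)
        c.mature = SequenceRecord("m", "A" * 24)
        c.arm = "5p"
        [mir] = hp.name_and_merge([c])
        s = hp.summarize_mirnas([mir])
        assert s["sizes"] == {24: 1}
        assert s["first_base_fractions"]["24nt"]["A"] == 1.0

    def test_intron_location(self):
        c = _candidate()
        c.window = GenomicInterval("chr1", 500, 600, "+")
        anns = [(GenomicInterval("chr1", 0, 2000, "+"), "gene"),
                (GenomicInterval("chr1", 0, 300, "+"), "exon")]
        assert hp.classify_location(c.window, anns) == "intron"
        anns.append((GenomicInterval("chr1", 450, 700, "+"), "exon"))
        assert hp.classify_location(c.window, anns) == "exon"
        assert hp.classify_location(GenomicInterval("chr1", 5000, 5100, "+"),
                                    anns) == "intergenic"

    def test_first_base_bias_recovered_on_large_catalog(self):
        from seedmir.simulate import SimulationConfig, _mature_seq
        rng = np.random.default_rng(3)
        cfg = SimulationConfig()
        catalog = []
        for i in range(500):
            c = _candidate(mature_len=24)
            c.mature = SequenceRecord("m", _mature_seq(rng, 24, cfg))
            c.window = GenomicInterval("chr1", i * 200 + 1, i * 200 + 101, "+")
            catalog.append(c)
        summary = hp.summarize_mirnas(hp.name_and_merge(catalog))
        frac_a = summary["first_base_fractions"]["24nt"].get("A", 0.0)
        assert abs(frac_a - 0.662) <= 0.04


class TestStarSuppression:
    def test_star_strand_with_fewer_reads_is_dropped(self):
        mature = _candidate()
        mature.mature = SequenceRecord("m", "A" * 21)
        mature.star = SequenceRecord("s", "C" * 21)
        mature.support = np.array([100, 80, 60])
        star = _candidate()
        star.mature = SequenceRecord("m2", "C" * 21)
        star.support = np.array([10, 8, 6])
        kept = hp.suppress_star_candidates([mature, star])
        assert kept == [mature]


class TestNussinovOracle:
    def test_planted_precursors_pair_at_least_fifteen(self, small_bundle):
        ref = small_bundle["ref"]
        g = ref.genome.residues
        for m in ref.registry.planted_mirnas:
            if not (m.intended_pass or m.category == "known"):
                continue
            prec = g[m.precursor.start:m.precursor.end]
            assert nussinov_max_pairs(prec) >= 15
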