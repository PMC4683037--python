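"""miRNA-target duplex scoring, transcriptome scanning, degradome
confirmation and cross-method overlap.

A target site is an ungapped antiparallel duplex between a miRNA and an
equal-length transcript window, scored against six complementarity rules
(G:U wobble counts as half a mismatch in the totals and as a non-match for
the adjacency rules):

  1. total mismatch score <= 4;
  2. no more than two consecutive non-matching positions;
  3. no adjacent non-matches within miRNA positions 2-12;
  4. perfect matches at positions 10 and 11;
  5. mismatch score over positions 1-12 <= 2.5;
  6. duplex hybridisation energy at least 75% (in magnitude) of the
     perfectly complementary duplex.

Cleavage is assigned opposite miRNA positions 10-11, and degradome support
for a site is a binomial tail test of the 5'-end tag pile-up at those two
transcript positions against a uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io import SequenceRecord

MAX_TOTAL_MISMATCH = 4.0
MAX_ADJACENT_RUN = 2
SEED_REGION = (2, 12)        # 1-based inclusive, miRNA 5' end
CLEAVAGE_POSITIONS = (10, 11)  # 1-based miRNA positions
MAX_SEED_MISMATCH = 2.5
MIN_ENERGY_RATIO = 0.75
DEGRADOME_ALPHA = 0.05
GU_WEIGHT = 0.5

RULE_NAMES = ("total_mismatch", "adjacent_run", "seed_adjacent",
              "cleavage_match", "seed_mismatch", "energy_ratio")

# Watson-Crick nearest-neighbor stack free energies (kcal/mol, 37 degC),
# keyed by the 5'->3' miRNA-strand dinucleotide (DNA alphabet, T==U).
NN_STACK = {
    "AA": -0.93, "AT": -1.10, "AC": -2.24, "AG": -2.08,
    "TA": -1.33, "TT": -0.93, "TC": -2.35, "TG": -2.11,
    "CA": -2.11, "CT": -2.08, "CC": -3.26, "CG": -2.36,
    "GA": -2.35, "GT": -2.24, "GC": -3.42, "GG": -3.26,
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class DuplexAlignment:
    mirna: str                 # 5'->3'
    site: str                  # 5'->3' on the transcript
    states: list[str]          # per miRNA position: match / GU / mismatch
    mismatch_score: float
    duplex_energy: float
    perfect_energy: float

    @property
    def energy_ratio(self) -> float:
        if self.perfect_energy == 0:
            return 0.0
        return abs(self.duplex_energy) / abs(self.perfect_energy)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    span: tuple[int, int]      # 0-based half-open on the transcript
    alignment: DuplexAlignment
    rule_verdicts: dict[str, bool]
    cleavage_position: int     # transcript coordinate opposite miRNA pos 10
    methods: set[str] = field(default_factory=set)

    @property
    def passes(self) -> bool:
        return all(self.rule_verdicts.values())

    @property
    def key(self) -> tuple[str, str]:
        return self.mirna_id, self.transcript_id


@dataclass
class DegradomeEvidence:
    site: TargetSite
    tags_at_slice: int
    tags_total: int
    p_value: float | None
    confirmed: bool


# ---------------------------------------------------------------------------
# Alignment and scoring

def _pair_state(m: str, s: str) -> str:
    if s == _COMP[m] and m != "N":
        return "match"
    if (m, s) in (("G", "T"), ("T", "G")):
        return "GU"
    return "mismatch"


def align_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Ungapped antiparallel alignment: miRNA position i (1-based) pairs site
    position L+1-i. Site is given 5'->3' on the transcript."""
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal lengths")
    L = len(mirna)
    states = [_pair_state(mirna[i], site[L - 1 - i]) for i in range(L)]
    score = states.count("mismatch") + GU_WEIGHT * states.count("GU")
    energy = duplex_energy(mirna, states)
    perfect = perfect_duplex_energy(mirna)
    return DuplexAlignment(mirna, site, states, score, energy, perfect)


def duplex_energy(mirna: str, states: list[str]) -> float:
    """Nearest-neighbor hybridisation energy: only stacks between adjacent
    Watson-Crick matched positions contribute; mismatch and G:U positions
    stabilise nothing."""
    e = 0.0
    for i in range(len(mirna) - 1):
        if states[i] == "match" and states[i + 1] == "match":
            e += NN_STACK[mirna[i:i + 2].replace("N", "A")]
    return round(e, 2)


def perfect_duplex_energy(mirna: str) -> float:
    return duplex_energy(mirna, ["match"] * len(mirna))


def score_rules(a: DuplexAlignment) -> dict[str, bool]:
    """The six duplex rules; site passes when all hold."""
    nm = [s != "match" for s in a.states]
    L = len(nm)
    run = max_run = 0
    for flag in nm:
        run = run + 1 if flag else 0
        max_run = max(max_run, run)
    lo, hi = SEED_REGION  # 1-based inclusive -> indices lo-1 .. hi-1
    seed_adjacent = any(
        nm[i] and nm[i + 1] for i in range(lo - 1, min(hi - 1, L - 1))
    )
    p10, p11 = CLEAVAGE_POSITIONS
    seed_states = a.states[:12]
    seed_score = (seed_states.count("mismatch")
                  + GU_WEIGHT * seed_states.count("GU"))
    verdicts = {
        "total_mismatch": a.mismatch_score <= MAX_TOTAL_MISMATCH,
        "adjacent_run": max_run <= MAX_ADJACENT_RUN,
        "seed_adjacent": not seed_adjacent,
        "cleavage_match": (L >= p11 and a.states[p10 - 1] == "match"
                           and a.states[p11 - 1] == "match"),
        "seed_mismatch": seed_score <= MAX_SEED_MISMATCH,
        "energy_ratio": a.energy_ratio >= MIN_ENERGY_RATIO,
    }
    return verdicts


# ---------------------------------------------------------------------------
# Transcriptome scanning (vectorised, with per-site verification objects)

def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


def scan_transcripts(mirnas: list[SequenceRecord],
                     transcripts: list[SequenceRecord],
                     method: str = "rule_scorer",
                     min_energy_ratio: float = MIN_ENERGY_RATIO,
                     max_total_mismatch: float = MAX_TOTAL_MISMATCH) -> list[TargetSite]:
    """Evaluate every length-L window of every transcript against every miRNA
    and return the sites passing all six rules.

    The two threshold arguments allow stricter parameter presets while
    keeping the same rule machinery.
    """
    sites: list[TargetSite] = []
    for tr in transcripts:
        t = _encode(tr.residues)
        T = len(t)
        for mir in mirnas:
            m = _encode(mir.residues)
            L = len(m)
            if T < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
            # win[w, i] = transcript base pairing miRNA position i+1
            comp = np.where(m < 4, 3 - m, np.int8(-1))
            match = win == comp[None, :]
            gu = (((m == 2)[None, :] & (win == 3))
                  | ((m == 3)[None, :] & (win == 2)))
            mm = ~match & ~gu
            nonmatch = mm | gu
            score = mm.sum(1) + GU_WEIGHT * gu.sum(1)
            r1 = score <= max_total_mismatch
            r2 = ~np.any(
                nonmatch[:, :-2] & nonmatch[:, 1:-1] & nonmatch[:, 2:], axis=1
            ) if L >= 3 else np.ones(len(win), bool)
            lo, hi = SEED_REGION
            sl = nonmatch[:, lo - 1:hi]
            r3 = ~np.any(sl[:, :-1] & sl[:, 1:], axis=1)
            r4 = match[:, CLEAVAGE_POSITIONS[0] - 1] & match[:, CLEAVAGE_POSITIONS[1] - 1]
            r5 = (mm[:, :12].sum(1) + GU_WEIGHT * gu[:, :12].sum(1)) <= MAX_SEED_MISMATCH
            survivors = np.flatnonzero(r1 & r2 & r3 & r4 & r5)
            for w in survivors:
                start = int(w)
                site_seq = tr.residues[start:start + L]
                aln = align_duplex(mir.residues, site_seq)
                verdicts = score_rules(aln)
                verdicts["total_mismatch"] = aln.mismatch_score <= max_total_mismatch
                verdicts["energy_ratio"] = aln.energy_ratio >= min_energy_ratio
                if not all(verdicts.values()):
                    continue
                # transcript position pairing miRNA position 10
                cleavage = start + L - CLEAVAGE_POSITIONS[0]
                sites.append(TargetSite(
                    mirna_id=mir.id, transcript_id=tr.id,
                    span=(start, start + L), alignment=aln,
                    rule_verdicts=verdicts, cleavage_position=cleavage,
                    methods={method},
                ))
    return sites


# ---------------------------------------------------------------------------
# Degradome confirmation

def degradome_confirm(site: TargetSite, tags: pd.DataFrame, transcript_length: int,
                      alpha: float = DEGRADOME_ALPHA) -> DegradomeEvidence:
    """Binomial tail test of the 5'-end tag pile-up at the cleavage slice.

    tags: columns (transcript, position, count), positions 0-based 5' ends.
    The slice covers the transcript positions opposite miRNA positions 10 and
    11, so the per-tag success probability under uniformity is
    2/transcript_length.
    """
    sub = tags[tags["transcript"] == site.transcript_id]
    total = int(sub["count"].sum())
    if total == 0:
        return DegradomeEvidence(site, 0, 0, None, False)
    slice_positions = {site.cleavage_position, site.cleavage_position - 1}
    at_slice = int(sub[sub["position"].isin(slice_positions)]["count"].sum())
    p = float(binom.sf(at_slice - 1, total, 2.0 / transcript_length))
    return DegradomeEvidence(site, at_slice, total, p, p < alpha)


# ---------------------------------------------------------------------------
# Method overlap (Venn counts)

def overlap_methods(site_sets: dict[str, set[tuple[str, str]]]) -> dict[str, int]:
    """Counts of (miRNA, transcript) pairs per exclusive membership pattern.

    Keys are '&'-joined sorted method subsets; totals are conserved.
    """
    methods = sorted(site_sets)
    universe: set[tuple[str, str]] = set().union(*site_sets.values()) if site_sets else set()
    counts: dict[str, int] = {}
    for pair in universe:
        members = tuple(m for m in methods if pair in site_sets[m])
        key = "&".join(members)
        counts[key] = counts.get(key, 0) + 1
    return counts
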