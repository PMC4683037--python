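"""Precursor hairpin extraction and novel-miRNA calling.

A genomic window around each unannotated mapped read is folded, trimmed to the
maximal stem-loop containing the mature sequence, and scored with the hairpin
metrics used for plant pre-miRNA filtering: MFE (kcal/mol), AMFE (|MFE| per
100 nt) and MFEI (AMFE divided by the G+C percentage; genuine plant
pre-miRNAs typically exceed 0.85).

Novel-miRNA calling applies four criteria:
  1. mature length within 20-24 nt;
  2. a classical fold-back precursor of at least 45 nt (operationalised as
     >=60% of mature bases paired, all partners on the opposite arm of a
     single stem-loop);
  3. more than five reads in at least one library;
  4. MFEI > 0.85, or the complementary miRNA* observed in the read set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import fold
from .io import GenomicInterval, SecondaryStructure, SequenceRecord, revcomp

DEFAULT_FLANK = 150
MFEI_THRESHOLD = 0.85
MATURE_LENGTH_RANGE = (20, 24)
MIN_PRECURSOR_LENGTH = 45
MIN_READS = 5          # criterion 3: strictly greater than this in >=1 library
PAIRED_FRACTION = 0.60  # fold-back: fraction of mature bases that must pair
HIT_MERGE_DISTANCE = 50

CRITERIA = ("mature_length", "fold_back", "read_support", "mfei_or_star")


@dataclass
class PrecursorCandidate:
    window: GenomicInterval            # trimmed precursor, genomic coordinates
    sequence: str                      # precursor sequence, 5'->3' on its strand
    structure: SecondaryStructure
    mature: SequenceRecord
    mature_offset: int                 # offset of mature within `sequence`
    gc: float                          # percent
    amfe: float
    mfei: float
    arm: str | None = None             # {5p, 3p}
    fold_back: bool = False
    star: SequenceRecord | None = None
    star_observed: bool = False
    support: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def passes(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


@dataclass
class NovelMiRNA:
    name: str
    mature: SequenceRecord
    precursors: list[PrecursorCandidate]


# ---------------------------------------------------------------------------
# Window extraction

def extract_window(hit: GenomicInterval, genome: SequenceRecord,
                   flank: int = DEFAULT_FLANK) -> tuple[str, GenomicInterval, int]:
    """Extract the +/- flank window around a read hit, clipped to chromosome ends.

    Returns (window sequence 5'->3' on the hit strand, forward-coordinate
    window interval, offset of the mature read within the returned sequence).
    """
    glen = len(genome.residues)
    start = max(0, hit.start - flank)
    end = min(glen, hit.end + flank)
    seq = genome.residues[start:end]
    if hit.strand == "+":
        offset = hit.start - start
    else:
        seq = revcomp(seq)
        offset = end - hit.end
    return seq, GenomicInterval(hit.chrom, start, end, hit.strand), offset


# ---------------------------------------------------------------------------
# Hairpin geometry

def _walk_inward(pt: np.ndarray, i: int, j: int) -> tuple[int, int] | None:
    """From pair (i, j) walk to the innermost pair of a simple stem.

    Returns the innermost pair, or None if the enclosed region branches into
    more than one helix (not a simple stem-loop).
    """
    while True:
        p = None
        for k in range(i + 1, j):
            if pt[k] != -1:
                p = k
                break
        if p is None:
            return i, j  # terminal loop reached
        q = pt[p]
        if q <= p or q >= j:
            return None
        # everything between q and j must be unpaired, else branching
        if any(pt[k] != -1 for k in range(q + 1, j)):
            return None
        i, j = p, q


def _walk_outward(pt: np.ndarray, i: int, j: int) -> tuple[int, int]:
    """Extend pair (i, j) outward through bulges/interior loops to the
    outermost pair of the enclosing stem."""
    n = len(pt)
    while True:
        p = None
        for k in range(i - 1, -1, -1):
            if pt[k] != -1:
                p = k
                break
        if p is None or pt[p] <= j or pt[p] >= n:
            return i, j
        q = pt[p]
        if any(pt[k] != -1 for k in range(j + 1, q)):
            return i, j
        i, j = p, q


def locate_hairpin(structure: SecondaryStructure, mature_start: int,
                   mature_end: int) -> dict:
    """Trim to the maximal simple stem-loop containing the mature and decide
    fold-back status.

    Returns dict with keys: fold_back, prec_start, prec_end (half-open, window
    coordinates), arm, paired_fraction.
    """
    pt = structure.pair_table()
    mature_pos = range(mature_start, mature_end)
    paired = [i for i in mature_pos if pt[i] != -1]
    L = mature_end - mature_start
    out = {
        "fold_back": False, "prec_start": mature_start, "prec_end": mature_end,
        "arm": None, "paired_fraction": len(paired) / L if L else 0.0,
    }
    if not paired or len(paired) / L < PAIRED_FRACTION:
        return out
    partners = [int(pt[i]) for i in paired]
    # all partners strictly on one side of the mature
    if not (max(partners) < mature_start or min(partners) > mature_end - 1):
        return out
    arm = "5p" if min(partners) > mature_end - 1 else "3p"
    # seed pair: the innermost (loop-proximal) pair of the mature helix
    if arm == "5p":
        a = max(paired)
        b = int(pt[a])
    else:
        b = min(paired)
        a = int(pt[b])
    inner = _walk_inward(pt, a, b)
    if inner is None:
        return out
    # seed outward walk from the outermost mature pair
    if arm == "5p":
        i0 = min(paired)
        j0 = int(pt[i0])
    else:
        j0 = max(paired)
        i0 = int(pt[j0])
    i_out, j_out = _walk_outward(pt, i0, j0)
    # partners of all paired mature bases must fall inside the trimmed hairpin
    if min(partners + paired) < i_out or max(partners + paired) > j_out:
        return out
    out.update(fold_back=True, prec_start=i_out, prec_end=j_out + 1, arm=arm)
    return out


# ---------------------------------------------------------------------------
# Metrics

def gc_percent(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for b in sequence if b in "GC") / len(sequence)


def compute_mfei(mfe: float, length: int, gc: float) -> tuple[float, float]:
    """AMFE = |MFE| / length x 100; MFEI = AMFE / GC%."""
    if length <= 0:
        raise ValueError("non-positive length")
    if gc <= 0:
        raise ValueError("MFEI undefined for GC = 0")
    amfe = abs(mfe) / length * 100.0
    return amfe, amfe / gc


# ---------------------------------------------------------------------------
# miRNA* detection

def find_star(window_seq: str, structure: SecondaryStructure, mature_start: int,
              mature_end: int) -> str | None:
    """Star sequence pairing the mature, with canonical 2-nt 3' overhangs.

    Returns None when the mature is mostly unpaired (no duplex defined).
    """
    pt = structure.pair_table()
    paired = [i for i in range(mature_start, mature_end) if pt[i] != -1]
    L = mature_end - mature_start
    if len(paired) < 0.5 * L:
        return None
    partners = [int(pt[i]) for i in paired]
    if not (max(partners) < mature_start or min(partners) > mature_end - 1):
        return None
    # Project the duplex geometry from the outermost paired mature bases.
    # Antiparallel pairing makes the same formula valid for either arm: the
    # star 5' end sits opposite mature position end-3 (2-nt mature 3'
    # overhang) and the star 3' end runs 2 nt past the partner of the mature
    # 5' end (2-nt star 3' overhang).
    i0 = min(paired)                      # 5'-most paired mature base
    j0 = int(pt[i0])                      # its partner (largest partner index)
    i1 = max(paired)                      # 3'-most paired mature base
    j1 = int(pt[i1])                      # its partner (smallest partner index)
    star_start = j1 - ((mature_end - 3) - i1)
    star_end = j0 + (i0 - mature_start) + 3
    star_start = max(0, star_start)
    star_end = min(len(window_seq), star_end)
    if star_end - star_start < L - 4:
        return None
    return window_seq[star_start:star_end]


# ---------------------------------------------------------------------------
# Candidate construction and criteria

def build_candidate(hit: GenomicInterval, genome: SequenceRecord,
                    mature_seq: str, flank: int = DEFAULT_FLANK) -> PrecursorCandidate | None:
    """Fold the flanked window and trim to the precursor hairpin."""
    window_seq, window, offset = extract_window(hit, genome, flank=flank)
    try:
        structure = fold(window_seq)
    except ValueError:
        return None
    geom = locate_hairpin(structure, offset, offset + len(mature_seq))
    s, e = geom["prec_start"], geom["prec_end"]
    prec_seq = window_seq[s:e]
    # re-fold the trimmed precursor so MFE refers to the reported sequence
    if geom["fold_back"] and len(prec_seq) >= 10:
        prec_struct = fold(prec_seq)
    else:
        prec_struct = SecondaryStructure("." * len(prec_seq), 0.0)
    if hit.strand == "+":
        g_start, g_end = window.start + s, window.start + e
    else:
        g_start, g_end = window.end - e, window.end - s
    gc = gc_percent(prec_seq)
    if gc > 0 and len(prec_seq) > 0:
        amfe, mfei = compute_mfei(prec_struct.mfe, len(prec_seq), gc)
    else:
        amfe, mfei = 0.0, 0.0
    star = find_star(window_seq, structure, offset, offset + len(mature_seq))
    cand = PrecursorCandidate(
        window=GenomicInterval(hit.chrom, g_start, g_end, hit.strand),
        sequence=prec_seq,
        structure=prec_struct,
        mature=SequenceRecord(id="mature", residues=mature_seq),
        mature_offset=offset - s,
        gc=gc, amfe=amfe, mfei=mfei,
        arm=geom["arm"], fold_back=geom["fold_back"],
        star=SequenceRecord(id="star", residues=star) if star else None,
    )
    return cand


def apply_novel_criteria(candidate: PrecursorCandidate,
                         counts: np.ndarray) -> dict[str, bool]:
    """The four novel-miRNA criteria; overall pass is their conjunction."""
    lo, hi = MATURE_LENGTH_RANGE
    verdicts = {
        "mature_length": lo <= len(candidate.mature.residues) <= hi,
        "fold_back": candidate.fold_back and candidate.length >= MIN_PRECURSOR_LENGTH,
        "read_support": bool(np.max(counts) > MIN_READS) if len(counts) else False,
        "mfei_or_star": candidate.mfei > MFEI_THRESHOLD or candidate.star_observed,
    }
    candidate.verdicts = verdicts
    candidate.support = np.asarray(counts, dtype=np.int64)
    return verdicts


def merge_hits(hits: list[GenomicInterval],
               distance: int = HIT_MERGE_DISTANCE) -> list[GenomicInterval]:
    """Collapse same-strand hits closer than `distance` to their first locus."""
    kept: list[GenomicInterval] = []
    for hit in sorted(hits, key=lambda h: (h.chrom, h.strand, h.start)):
        if kept and kept[-1].chrom == hit.chrom and kept[-1].strand == hit.strand \
                and hit.start - kept[-1].start < distance:
            continue
        kept.append(hit)
    return kept


def discover(read_hits: dict[str, list[GenomicInterval]],
             counts: dict[str, np.ndarray],
             genome: SequenceRecord,
             read_set: set[str] | None = None,
             flank: int = DEFAULT_FLANK) -> list[PrecursorCandidate]:
    """Run candidate extraction + criteria over unannotated mapped reads.

    read_set: all observed read sequences (for miRNA* detection); defaults to
    the keys of `read_hits`.
    """
    if read_set is None:
        read_set = set(read_hits)
    candidates: list[PrecursorCandidate] = []
    for seq in sorted(read_hits):
        for hit in merge_hits(read_hits[seq]):
            cand = build_candidate(hit, genome, seq, flank=flank)
            if cand is None:
                continue
            if cand.star is not None:
                cand.star_observed = cand.star.residues in read_set
            apply_novel_criteria(cand, counts[seq])
            candidates.append(cand)
    return candidates


def suppress_star_candidates(candidates: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Drop candidates that are the star strand of a better-supported
    candidate at the same locus: a mature/star duplex yields one miRNA, and
    the strand with more reads is the mature."""
    star_of: dict[str, int] = {}
    for cand in candidates:
        if cand.star is not None:
            prev = star_of.get(cand.star.residues, -1)
            star_of[cand.star.residues] = max(prev, int(cand.support.max())
                                              if len(cand.support) else 0)
    kept = []
    for cand in candidates:
        own = int(cand.support.max()) if len(cand.support) else 0
        if cand.mature.residues in star_of and star_of[cand.mature.residues] > own:
            continue
        kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Naming and catalog summaries

def name_and_merge(passing: list[PrecursorCandidate],
                   prefix: str = "OsmiR-") -> list[NovelMiRNA]:
    """Merge identical matures into one miRNA; serials follow first genomic
    coordinate; precursor suffixes -1, -2, ... by coordinate."""
    groups: dict[str, list[PrecursorCandidate]] = {}
    for cand in passing:
        groups.setdefault(cand.mature.residues, []).append(cand)
    keyed = []
    for mature_seq, cands in groups.items():
        cands.sort(key=lambda c: (c.window.chrom, c.window.start, c.window.strand))
        first = cands[0].window
        keyed.append(((first.chrom, first.start, mature_seq), mature_seq, cands))
    keyed.sort(key=lambda t: t[0])
    catalog = []
    for serial, (_, mature_seq, cands) in enumerate(keyed, 1):
        name = f"{prefix}{serial}"
        for k, cand in enumerate(cands, 1):
            cand.mature = SequenceRecord(
                id=f"{name}-{k}" if len(cands) > 1 else name,
                residues=mature_seq,
            )
        catalog.append(NovelMiRNA(
            name=name,
            mature=SequenceRecord(id=name, residues=mature_seq),
            precursors=cands,
        ))
    return catalog


def classify_location(window: GenomicInterval,
                      annotations: list[tuple[GenomicInterval, str]]) -> str:
    """Intergenic / exon / intron class of a precursor locus."""
    in_gene = False
    for iv, ftype in annotations:
        if not window.overlaps(iv):
            continue
        f = ftype.lower()
        if f in ("cds", "exon"):
            return "exon"
        if f == "intron":
            return "intron"
        if f in ("gene", "mrna"):
            in_gene = True
    return "intron" if in_gene else "intergenic"


def summarize_mirnas(catalog: list[NovelMiRNA],
                     annotations: list[tuple[GenomicInterval, str]] | None = None) -> dict:
    """Size distribution, per-length-class first-base fractions, genome
    location classes, and arm distribution of a miRNA catalog."""
    sizes: dict[int, int] = {}
    first_base: dict[str, dict[str, int]] = {}
    locations: dict[str, int] = {}
    arms: dict[str, int] = {}
    for mir in catalog:
        L = len(mir.mature.residues)
        sizes[L] = sizes.get(L, 0) + 1
        cls = "24nt" if L == 24 else "short"
        base = mir.mature.residues[0].replace("T", "U")
        first_base.setdefault(cls, {}).setdefault(base, 0)
        first_base[cls][base] += 1
        if annotations is not None and mir.precursors:
            loc = classify_location(mir.precursors[0].window, annotations)
            locations[loc] = locations.get(loc, 0) + 1
        for prec in mir.precursors:
            if prec.arm:
                arms[prec.arm] = arms.get(prec.arm, 0) + 1
    first_frac = {
        cls: {b: n / sum(d.values()) for b, n in d.items()}
        for cls, d in first_base.items()
    }
    return {
        "sizes": dict(sorted(sizes.items())),
        "first_base_fractions": first_frac,
        "locations": locations,
        "arms": arms,
    }
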