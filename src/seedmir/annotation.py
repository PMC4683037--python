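"""Length filtering, exact genome mapping, and structural-RNA read classification.

Reads are filtered to 18-30 nt, mapped perfectly to the genome on both
strands, and partitioned into the non-coding categories of a small-RNA
sequencing summary table: known miRNA, rRNA, tRNA, snoRNA, snRNA and
unannotated ("others"). Known-miRNA matching allows up to two substitutions
against a mature catalog (equal length, no indels); the structural RNA
categories require an exact substring match of a reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .io import CountTable, GenomicInterval, SequenceRecord, hamming, revcomp

LENGTH_RANGE = (18, 30)
MAX_MIRNA_MISMATCHES = 2

NONCODING_CATEGORIES = ("known_miRNA", "rRNA", "tRNA", "snoRNA", "snRNA")
DEFAULT_PRECEDENCE = NONCODING_CATEGORIES  # known miRNA wins collisions
STRUCTURAL_FIRST_PRECEDENCE = ("rRNA", "tRNA", "snoRNA", "snRNA", "known_miRNA")


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Half-up rounded percentage; 0.0 when the denominator is zero."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class AnnotatedRead:
    sequence: str
    counts: np.ndarray
    hits: list[GenomicInterval] = field(default_factory=list)
    category: str = "other"
    cds_overlap: bool = False


# ---------------------------------------------------------------------------

def length_filter(reads: CountTable, min_len: int = LENGTH_RANGE[0],
                  max_len: int = LENGTH_RANGE[1]) -> CountTable:
    """Retain sequences with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    out = CountTable(library_ids=list(reads.library_ids),
                     clean_totals=reads.clean_totals.copy())
    for seq, vec in reads.counts.items():
        if min_len <= len(seq) <= max_len:
            out.add(seq, vec)
    return out


class GenomeIndex:
    """Exact-substring index of a genome, per query length, both strands."""

    def __init__(self, genome: SequenceRecord):
        self.genome = genome
        self._fwd: dict[int, dict[str, list[int]]] = {}
        self._rev: dict[int, dict[str, list[int]]] = {}

    def _build(self, L: int) -> None:
        g = self.genome.residues
        fwd: dict[str, list[int]] = {}
        rev: dict[str, list[int]] = {}
        for i in range(len(g) - L + 1):
            sub = g[i:i + L]
            if "N" in sub:
                continue
            fwd.setdefault(sub, []).append(i)
            rev.setdefault(revcomp(sub), []).append(i)
        self._fwd[L], self._rev[L] = fwd, rev

    def hits(self, seq: str) -> list[GenomicInterval]:
        if "N" in seq:
            return []
        L = len(seq)
        if L not in self._fwd:
            self._build(L)
        chrom = self.genome.id
        out = [GenomicInterval(chrom, i, i + L, "+")
               for i in self._fwd[L].get(seq, [])]
        out += [GenomicInterval(chrom, i, i + L, "-")
                for i in self._rev[L].get(seq, [])]
        out.sort(key=lambda iv: (iv.start, iv.strand))
        return out


def map_exact(reads: CountTable, genome: SequenceRecord) -> dict[str, list[GenomicInterval]]:
    """All perfect occurrences of each read on both genome strands.

    Reads with zero hits map to an empty list. N never matches.
    """
    index = GenomeIndex(genome)
    return {seq: index.hits(seq) for seq in reads.counts}


# ---------------------------------------------------------------------------

def _matches_known(seq: str, by_length: dict[int, list[str]]) -> bool:
    for cat_seq in by_length.get(len(seq), []):
        if hamming(seq, cat_seq) <= MAX_MIRNA_MISMATCHES:
            return True
    return False


def classify(reads: CountTable,
             hits: dict[str, list[GenomicInterval]],
             references: dict[str, list[SequenceRecord]],
             known_mirnas: list[SequenceRecord],
             cds: list[tuple[GenomicInterval, str]] | None = None,
             precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> list[AnnotatedRead]:
    """Assign each genome-mapped read to exactly one category.

    references: mapping of category (rRNA/tRNA/snoRNA/snRNA) to reference
    sequences; a read matches when it is an exact substring of any reference.
    Unmapped reads are excluded (category applies to mapped reads only).
    """
    for cat in ("rRNA", "tRNA", "snoRNA", "snRNA"):
        if cat not in references:
            raise ValueError(f"missing reference set for category {cat!r}")
    by_length: dict[int, list[str]] = {}
    for rec in known_mirnas:
        by_length.setdefault(len(rec.residues), []).append(rec.residues)
    cds_intervals = [iv for iv, f in (cds or []) if f.upper() == "CDS"]
    ref_seqs = {cat: [r.residues for r in recs] for cat, recs in references.items()}

    out: list[AnnotatedRead] = []
    for seq in sorted(reads.counts):
        read_hits = hits.get(seq, [])
        if not read_hits:
            continue
        category = "other"
        for cat in precedence:
            if cat == "known_miRNA":
                matched = _matches_known(seq, by_length)
            else:
                matched = any(seq in ref for ref in ref_seqs[cat])
            if matched:
                category = cat
                break
        cds_overlap = any(h.overlaps(iv) for h in read_hits for iv in cds_intervals)
        out.append(AnnotatedRead(
            sequence=seq, counts=reads.counts[seq], hits=read_hits,
            category=category, cds_overlap=cds_overlap,
        ))
    return out


# ---------------------------------------------------------------------------
# Summary table (reads/unique counts and footnote-convention percentages)

SUMMARY_ROWS = (
    "sequences of 18-30 nt",
    "mapping to genome",
    "CDS matched",
    "non-coding total",
    "known miRNA",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "others",
)

_CATEGORY_TO_ROW = {
    "known_miRNA": "known miRNA", "rRNA": "rRNA", "tRNA": "tRNA",
    "snoRNA": "snoRNA", "snRNA": "snRNA", "other": "others",
}


def summarize(annotated: list[AnnotatedRead], filtered: CountTable) -> pd.DataFrame:
    """Per-library reads/unique counts and percentages for each summary row.

    Percentage conventions: the mapped and CDS rows are relative to the
    18-30 nt totals; each non-coding category's reads column is relative to
    the non-coding reads total; every unique-column percentage is relative to
    the reads count of the same cell.
    """
    libs = list(filtered.library_ids)
    nlib = len(libs)
    reads_tot = filtered.total_counts()
    uniq_tot = np.array([sum(1 for v in filtered.counts.values() if v[i] > 0)
                         for i in range(nlib)])

    def cell_counts(rows: list[AnnotatedRead]) -> tuple[np.ndarray, np.ndarray]:
        if not rows:
            z = np.zeros(nlib, dtype=np.int64)
            return z, z.copy()
        mat = np.stack([r.counts for r in rows])
        return mat.sum(axis=0), (mat > 0).sum(axis=0)

    mapped_reads, mapped_uniq = cell_counts(annotated)
    cds_rows = [r for r in annotated if r.cds_overlap]
    cds_reads, cds_uniq = cell_counts(cds_rows)
    noncoding = [r for r in annotated if not r.cds_overlap]
    nc_reads, _ = cell_counts(noncoding)

    records = []
    for lib_i, lib in enumerate(libs):
        def row(label, reads, uniq, reads_den, uniq_den=None):
            records.append({
                "row": label, "library": lib,
                "reads": int(reads), "reads_pct": percent(reads, reads_den),
                "unique": int(uniq),
                "unique_pct": percent(uniq, reads if uniq_den is None else uniq_den),
            })

        row("sequences of 18-30 nt", reads_tot[lib_i], uniq_tot[lib_i],
            reads_tot[lib_i], uniq_den=uniq_tot[lib_i])
        row("mapping to genome", mapped_reads[lib_i], mapped_uniq[lib_i],
            reads_tot[lib_i], uniq_den=uniq_tot[lib_i])
        row("CDS matched", cds_reads[lib_i], cds_uniq[lib_i],
            reads_tot[lib_i], uniq_den=uniq_tot[lib_i])
        nc_total = nc_reads[lib_i]
        records.append({
            "row": "non-coding total", "library": lib,
            "reads": int(nc_total), "reads_pct": percent(nc_total, nc_total),
            "unique": None, "unique_pct": None,
        })
        for cat in (*NONCODING_CATEGORIES, "other"):
            rows_cat = [r for r in noncoding if r.category == cat]
            c_reads, c_uniq = cell_counts(rows_cat)
            row(_CATEGORY_TO_ROW[cat], c_reads[lib_i], c_uniq[lib_i], nc_total)
    return pd.DataFrame.from_records(records)


def published_library_stats() -> pd.DataFrame:
    """The published per-library sequencing statistics (reads/unique counts)
    whose percentage conventions this module's summary reproduces."""
    with resources.files("seedmir.data").joinpath("library_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])
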