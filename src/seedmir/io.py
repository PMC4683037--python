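"""Shared sequence/coordinate types and readers/writers for the standard formats.

All coordinates are 0-based half-open on the forward strand; minus-strand
features keep forward coordinates plus a strand flag.  T and U are equivalent
in every comparison: residues are normalised to the DNA alphabet internally
and the original alphabet is remembered so output can round-trip.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files."""


def normalize_residues(residues: str) -> str:
    """Uppercase and map U->T. Raises on non-nucleotide characters."""
    seq = residues.strip().upper().replace("U", "T")
    if not seq:
        raise FormatError("empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length sequences; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""
    is_rna: bool = False  # original alphabet used U

    def __post_init__(self):
        if "U" in self.residues.upper():
            object.__setattr__(self, "is_rna", True)
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def output_residues(self) -> str:
        return to_rna(self.residues) if self.is_rna else self.residues


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CountTable:
    """Unique-sequence x library read counts plus per-library clean totals.

    ``counts`` maps sequence -> numpy int vector aligned with ``library_ids``;
    ``clean_totals`` is the total number of clean reads per library (the TPM
    denominator), which may exceed the sum of retained entries after filtering.
    """

    library_ids: list[str]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    clean_totals: np.ndarray | None = None

    def __post_init__(self):
        if self.clean_totals is None:
            self.clean_totals = np.zeros(len(self.library_ids), dtype=np.int64)
        self.clean_totals = np.asarray(self.clean_totals, dtype=np.int64)
        if len(self.clean_totals) != len(self.library_ids):
            raise ValueError("clean_totals length mismatch")

    def add(self, sequence: str, counts: Sequence[int]) -> None:
        vec = np.asarray(counts, dtype=np.int64)
        if vec.shape != (len(self.library_ids),):
            raise ValueError("count vector length mismatch")
        if (vec < 0).any():
            raise ValueError("negative counts")
        if sequence in self.counts:
            self.counts[sequence] = self.counts[sequence] + vec
        else:
            self.counts[sequence] = vec

    def total_counts(self) -> np.ndarray:
        if not self.counts:
            return np.zeros(len(self.library_ids), dtype=np.int64)
        return np.sum(list(self.counts.values()), axis=0)

    def n_unique(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            {s: v for s, v in self.counts.items()}, orient="index",
            columns=self.library_ids,
        )
        df.index.name = "sequence"
        return df

    @classmethod
    def merge(cls, tables: Sequence["CountTable"]) -> "CountTable":
        """Outer-join single/multi-library tables into one multi-library table."""
        library_ids: list[str] = []
        for t in tables:
            library_ids.extend(t.library_ids)
        if len(set(library_ids)) != len(library_ids):
            raise ValueError("duplicate library ids")
        merged = cls(library_ids=library_ids)
        totals = []
        offset = 0
        for t in tables:
            k = len(t.library_ids)
            for seq, vec in t.counts.items():
                full = np.zeros(len(library_ids), dtype=np.int64)
                full[offset:offset + k] = vec
                merged.add(seq, full)
            totals.append(t.clean_totals)
            offset += k
        merged.clean_totals = np.concatenate(totals)
        return merged


@dataclass(frozen=True)
class SecondaryStructure:
    dotbracket: str
    mfe: float

    def __post_init__(self):
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket")
            elif ch != ".":
                raise ValueError(f"invalid structure character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket")
        npairs = self.dotbracket.count("(")
        if npairs and self.mfe > 0:
            raise ValueError("paired structure with positive free energy")

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def pair_table(self) -> np.ndarray:
        """0-based partner index per position, -1 for unpaired."""
        pt = np.full(len(self.dotbracket), -1, dtype=np.int64)
        stack: list[int] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        return pt


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    U is normalised to T internally; the original alphabet is remembered.
    Duplicate ids and empty sequences are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if not raw:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=raw,
                description=rec.description[len(rec.id):].strip(),
                is_rna="U" in raw.upper(),
            )
        )
    if not records and path.stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            fh.write(rec.output_residues + "\n")


def _iter_raw_reads(path: Path) -> Iterable[str]:
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq)


def collapse_reads(path: str | Path, library_id: str) -> CountTable:
    """Collapse raw reads (FASTA or FASTQ by extension) to unique sequences.

    clean_total is the number of input reads; qualities are ignored.
    """
    path = Path(path)
    table = CountTable(library_ids=[library_id])
    tally: dict[str, int] = {}
    n = 0
    for raw in _iter_raw_reads(path):
        seq = normalize_residues(raw)
        tally[seq] = tally.get(seq, 0) + 1
        n += 1
    for seq, c in tally.items():
        table.add(seq, [c])
    table.clean_totals = np.array([n], dtype=np.int64)
    return table


def read_count_tsv(path: str | Path, clean_totals: Mapping[str, int] | None = None) -> CountTable:
    """Read a collapsed count TSV (column ``sequence`` + one column per library)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    if "sequence" not in df.columns:
        raise FormatError(f"{path}: missing 'sequence' column")
    libs = [c for c in df.columns if c != "sequence"]
    table = CountTable(library_ids=libs)
    for _, row in df.iterrows():
        table.add(normalize_residues(row["sequence"]), [int(row[c]) for c in libs])
    if clean_totals is not None:
        table.clean_totals = np.array([clean_totals[c] for c in libs], dtype=np.int64)
    else:
        table.clean_totals = table.total_counts()
    return table


def write_count_tsv(table: CountTable, path: str | Path) -> None:
    df = table.to_frame().reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations (GFF3, 1-based inclusive; BED, 0-based half-open)

def read_annotations(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read GFF3 or BED intervals (dialect by extension) into internal coordinates."""
    path = Path(path)
    ext = path.suffix.lower()
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if ext in (".gff", ".gff3"):
                    chrom, _source, ftype = fields[0], fields[1], fields[2]
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in "+-" else "+"
                elif ext == ".bed":
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    ftype = fields[3] if len(fields) > 3 else "region"
                    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
                else:
                    raise FormatError(f"{path}: unknown annotation extension {ext!r}")
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end after conversion")
            out.append((GenomicInterval(chrom, start, end, strand), ftype))
    return out


def write_gff3(features: Iterable[tuple[GenomicInterval, str, str]], path: str | Path,
               source: str = "seedmir") -> None:
    """Write (interval, feature_type, attributes) triples as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Tabular results

def write_results_tsv(table: pd.DataFrame, path: str | Path,
                      float_precision: int = 6) -> None:
    """Write a tabular result as TSV with header; missing values render as NA."""
    if table.columns.empty:
        raise ValueError("table has no columns")
    table.to_csv(
        path, sep="\t", index=False, na_rep="NA",
        float_format=f"%.{float_precision}g",
    )


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
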