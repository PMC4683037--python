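"""Synthetic reference, libraries, transcriptome and degradome with full
ground-truth bookkeeping.

The generator emulates the structure of a three-time-point (0/12/24 hours
after imbibition) embryo small-RNA experiment: a miniature genome hosting
structural-RNA genes and engineered miRNA hairpins; collapsed read libraries
with 21/24-nt abundance peaks, first-base bias and planted differential
profiles; a transcriptome with target sites instantiating chosen duplex
mismatch patterns; and degradome tags concentrated at canonical cleavage
slices.

Planted hairpins are built constructively (arm + loop + reverse complement
of the arm) and then verified in their final genomic context with the actual
discovery code: a candidate is accepted only when its criteria verdicts match
the intent, so every "pass" hairpin passes all four novel-miRNA criteria and
every decoy fails exactly its named criterion. Verification uses
rejection sampling and is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import hairpin as hp
from . import targets as tg
from .io import (CountTable, GenomicInterval, SequenceRecord, revcomp,
                 write_fasta)

BASES = "ACGT"


@dataclass
class SimulationConfig:
    genome_length: int = 60_000
    n_known_mirnas: int = 8
    n_novel_mirnas: int = 20
    n_decoy_hairpins: int = 5          # per violated-criterion class (4 classes)
    loop_length_range: tuple[int, int] = (8, 14)
    gc_target_range: tuple[float, float] = (0.40, 0.60)
    library_ids: tuple[str, ...] = ("0HAI", "12HAI", "24HAI")
    reads_per_library: int = 100_000
    size_class_mix: dict = field(default_factory=lambda: {
        "21": 0.40, "24": 0.35, "other": 0.25})
    first_base_bias: dict = field(default_factory=lambda: {
        "24nt": {"A": 0.662}, "short": {"T": 0.693}})
    differential_fraction: float = 0.3
    n_transcripts: int = 12
    site_rule_profile: tuple[str, ...] = (
        "perfect",
        "gu@5",
        "mm@5",
        "mm@10",                      # fails the position-10/11 rule
        "mm@3,mm@4",                  # adjacent seed mismatches
        "mm@1,gu@6,mm@15",
        "mm@1,mm@4,mm@7,mm@14,mm@17",  # five mismatches: fails the total
        "mm@13,mm@16,mm@19",
    )
    degradome_signal_fraction: float = 0.5
    degradome_tags_per_transcript: int = 200
    noise_fraction: float = 0.4
    n_noise_intergenic: int = 250
    n_noise_fragments: int = 350
    tpm_log_mean: float = np.log(800.0)
    tpm_log_sigma: float = 0.8
    tpm_clip: tuple[float, float] = (300.0, 5000.0)
    seed: int = 1

    def __post_init__(self):
        for name in ("differential_fraction", "degradome_signal_fraction",
                     "noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.size_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("size_class_mix must sum to 1")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        lo, hi = self.gc_target_range
        if not (0 < lo <= hi < 1):
            raise ValueError("invalid gc_target_range")


DECOY_CLASSES = ("mature_length", "fold_back", "read_support", "mfei_or_star")


@dataclass
class PlantedMiRNA:
    name: str
    mature: str
    precursor: GenomicInterval
    arm: str
    category: str                      # known / novel / decoy
    decoy_class: str | None = None     # criterion violated (decoys only)
    star: str | None = None
    star_planted: bool = False
    intended_pass: bool = True


@dataclass
class PlantedSite:
    mirna: str
    transcript: str
    span: tuple[int, int]
    pattern: str
    intended_verdicts: dict[str, bool] = field(default_factory=dict)
    expect_pass: bool = True
    cleavage_position: int = 0


@dataclass
class GroundTruthRegistry:
    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    planted_tpm: dict[str, list[float]] = field(default_factory=dict)
    fixed_counts: dict[str, list[int]] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    anti_pairs: list[tuple[str, str]] = field(default_factory=list)
    differential: dict[str, bool] = field(default_factory=dict)

    def by_name(self, name: str) -> PlantedMiRNA:
        return next(m for m in self.planted_mirnas if m.name == name)

    def pass_matures(self) -> set[str]:
        return {m.mature for m in self.planted_mirnas
                if m.category == "novel" and m.intended_pass}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "planted_mirnas": [
                {**asdict(m), "precursor": [m.precursor.chrom, m.precursor.start,
                                            m.precursor.end, m.precursor.strand]}
                for m in self.planted_mirnas
            ],
            "planted_tpm": self.planted_tpm,
            "fixed_counts": self.fixed_counts,
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "anti_pairs": self.anti_pairs,
            "differential": self.differential,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


@dataclass
class Reference:
    genome: SequenceRecord
    annotations: list[tuple[GenomicInterval, str]]
    references: dict[str, list[SequenceRecord]]
    known_catalog: list[SequenceRecord]
    registry: GroundTruthRegistry
    noise_intergenic: list[str] = field(default_factory=list)
    noise_fragments: list[str] = field(default_factory=list)
    transcripts: list[SequenceRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Sequence construction helpers

def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _mature_seq(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    cls = "24nt" if length == 24 else "short"
    bias = cfg.first_base_bias.get(cls, {})
    first = None
    for base, prob in bias.items():
        if rng.random() < prob:
            first = base.replace("U", "T")
        break
    if first is None:
        others = [b for b in BASES if b not in
                  {k.replace("U", "T") for k in bias}] or list(BASES)
        first = others[rng.integers(len(others))]
    gc = rng.uniform(*cfg.gc_target_range)
    return first + _random_seq(rng, length - 1, gc)


def _draw_mature_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    classes = list(cfg.size_class_mix)
    probs = np.array([cfg.size_class_mix[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    if cls == "other":
        return int(rng.choice([20, 22, 23]))
    return int(cls)


def _build_hairpin(rng: np.random.Generator, mature: str,
                   cfg: SimulationConfig, ext_len: int | None = None,
                   n_bulges: int = 0) -> str:
    """arm + loop + reverse complement of arm, mature at the 5' end (5p arm).

    Bulge mutations are restricted to positions pairing the arm extension so
    the mature stays fully paired.
    """
    if ext_len is None:
        ext_len = int(rng.integers(8, 13))
    gc = rng.uniform(*cfg.gc_target_range)
    ext = _random_seq(rng, ext_len, gc)
    arm = mature + ext
    loop = _random_seq(rng, int(rng.integers(*cfg.loop_length_range)), 0.3)
    arm2 = list(revcomp(arm))
    # arm2 pairs arm reversed: arm2[:ext_len] pairs the extension
    for _ in range(n_bulges):
        if ext_len == 0:
            break
        k = int(rng.integers(0, ext_len))
        arm2[k] = BASES[rng.integers(4)]
    return arm + loop + "".join(arm2)


def _build_weak_hairpin(rng: np.random.Generator, mature_len: int = 21) -> tuple[str, str]:
    """Fold-back hairpin engineered for a low folding-energy index.

    Alphabet {A, C} on the mature arm and {T, C} on the partner arm: A:T
    columns pair (weak), C columns cannot pair anything in the precursor, so
    the stem is real but energetically poor while the C content keeps G+C%
    up. Returns (precursor sequence, mature sequence).
    """
    pattern = []  # True = paired column
    pos = 0
    while pos < mature_len + 6:
        seg = int(rng.integers(6, 9))
        pattern.extend([True] * seg)
        pos += seg
        if pos < mature_len + 6:
            gap = int(rng.integers(2, 4))
            pattern.extend([False] * gap)
            pos += gap
    arm0 = "".join("A" if p else "C" for p in pattern)
    arm1 = "".join("T" if p else "C" for p in reversed(pattern))
    loop = "C" * int(rng.integers(8, 12))
    mature = arm0[:mature_len]
    return arm0 + loop + arm1, mature


# ---------------------------------------------------------------------------
# Hairpin verification in final genomic context

def _canonical_star(genome_seq: str, prec_start: int, prec_len: int,
                    mature_len: int) -> str:
    """Closed-form star of a perfect-stem hairpin whose mature opens the
    precursor: the 3' arm segment pairing the mature, with 2-nt 3' overhangs
    on both duplex ends."""
    s = prec_start + prec_len - mature_len + 2
    e = prec_start + prec_len + 2
    return genome_seq[s:e]


def _verify_planting(genome_prefix: str, hairpin_seq: str, right_ctx: str,
                     mature: str, counts: np.ndarray,
                     star_available: bool) -> tuple[dict[str, bool], hp.PrecursorCandidate | None]:
    """Run the real discovery code on the trial context; returns the criteria
    verdicts the candidate would receive (star_observed = star_available)."""
    trial = SequenceRecord(id="trial", residues=genome_prefix + hairpin_seq + right_ctx)
    m0 = len(genome_prefix) + hairpin_seq.find(mature)
    hit = GenomicInterval("trial", m0, m0 + len(mature), "+")
    cand = hp.build_candidate(hit, trial, mature)
    if cand is None:
        return {}, None
    cand.star_observed = star_available and cand.star is not None
    verdicts = hp.apply_novel_criteria(cand, counts)
    return verdicts, cand


_INTENT = {
    None: {c: True for c in hp.CRITERIA},  # pass hairpin
    "mature_length": {"mature_length": False, "fold_back": True,
                      "read_support": True, "mfei_or_star": True},
    "fold_back": {"mature_length": True, "fold_back": False,
                  "read_support": True, "mfei_or_star": True},
    "read_support": {"mature_length": True, "fold_back": True,
                     "read_support": False, "mfei_or_star": True},
    "mfei_or_star": {"mature_length": True, "fold_back": True,
                     "read_support": True, "mfei_or_star": False},
}


def _plant_hairpin(rng: np.random.Generator, genome: list[str], cfg: SimulationConfig,
                   name: str, category: str, decoy_class: str | None,
                   known_matures: list[str], star_planted: bool,
                   max_attempts: int = 400) -> PlantedMiRNA:
    """Propose hairpin + right context until the discovery code's verdicts in
    the final genomic context equal the intent; append to the genome."""
    prefix = "".join(genome)
    intent = _INTENT[decoy_class]
    counts = np.array([60, 60, 60])
    if decoy_class == "read_support":
        counts = np.array([5, 3, 2])
    for _ in range(max_attempts):
        if decoy_class == "mature_length":
            mature = _mature_seq(rng, 19, cfg)
            hp_seq = _build_hairpin(rng, mature, cfg)
        elif decoy_class == "fold_back":
            mature = _mature_seq(rng, 20, cfg)
            arm = mature[:17]
            loop = mature[17:20] + _random_seq(rng, 5, 0.3)
            hp_seq = arm + loop + revcomp(arm)
        elif decoy_class == "mfei_or_star":
            hp_seq, mature = _build_weak_hairpin(rng)
        else:  # pass hairpin (known/novel) or read_support decoy
            length = 21 if category == "known" else _draw_mature_length(rng, cfg)
            mature = _mature_seq(rng, length, cfg)
            hp_seq = _build_hairpin(rng, mature, cfg, n_bulges=int(rng.integers(0, 3)))
        # mature must be unique, unmistakable for a known miRNA, and absent
        # from the already-built genome
        if mature in prefix or revcomp(mature) in prefix or hp_seq.count(mature) != 1:
            continue
        collision = any(
            len(k) == len(mature) and
            sum(a != b for a, b in zip(k, mature)) <= 2
            for k in known_matures
        )
        if collision and category != "known":
            continue
        right_ctx = _random_seq(rng, 150, 0.45)
        star_ok = star_planted and decoy_class is None
        verdicts, cand = _verify_planting(prefix, hp_seq, right_ctx, mature,
                                          counts, star_ok)
        if verdicts != intent:
            continue
        start = len(prefix)
        genome.append(hp_seq)
        genome.append(right_ctx)
        star = None
        if cand is not None and cand.star is not None:
            star = cand.star.residues
        return PlantedMiRNA(
            name=name, mature=mature,
            precursor=GenomicInterval("chr1", start, start + len(hp_seq), "+"),
            arm="5p" if decoy_class != "mfei_or_star" else "5p",
            category=category, decoy_class=decoy_class,
            star=star, star_planted=star_ok and star is not None,
            intended_pass=decoy_class is None and category == "novel",
        )
    raise RuntimeError(f"could not plant hairpin {name} ({decoy_class}) "
                       f"after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Reference generation

def generate_reference(cfg: SimulationConfig) -> Reference:
    rng = np.random.default_rng(cfg.seed)
    registry = GroundTruthRegistry()
    genome: list[str] = [_random_seq(rng, 300, 0.45)]
    annotations: list[tuple[GenomicInterval, str]] = []
    references: dict[str, list[SequenceRecord]] = {}

    # structural-RNA genes, embedded so their fragments map to the genome
    ncrna_plan = {"rRNA": [900, 1400], "tRNA": [72, 75, 78, 80],
                  "snoRNA": [110, 130, 150], "snRNA": [140, 160, 180]}
    for cat, lengths in ncrna_plan.items():
        references[cat] = []
        for k, L in enumerate(lengths, 1):
            seq = _random_seq(rng, L, 0.52)
            start = sum(len(s) for s in genome)
            genome.append(seq)
            genome.append(_random_seq(rng, 150, 0.45))
            iv = GenomicInterval("chr1", start, start + L, "+")
            annotations.append((iv, cat))
            references[cat].append(SequenceRecord(id=f"{cat}-{k}", residues=seq))

    # protein-coding genes with CDS, for the CDS-matched row
    for k in range(1, 4):
        L = int(rng.integers(900, 1500))
        seq = _random_seq(rng, L, 0.5)
        start = sum(len(s) for s in genome)
        genome.append(seq)
        genome.append(_random_seq(rng, 150, 0.45))
        annotations.append((GenomicInterval("chr1", start, start + L, "+"), "gene"))
        annotations.append(
            (GenomicInterval("chr1", start + 100, start + L - 100, "+"), "CDS"))

    known_matures: list[str] = []
    known_catalog: list[SequenceRecord] = []
    for k in range(1, cfg.n_known_mirnas + 1):
        planted = _plant_hairpin(rng, genome, cfg, f"known-miR-{k}", "known",
                                 None, known_matures, star_planted=False)
        known_matures.append(planted.mature)
        known_catalog.append(SequenceRecord(id=planted.name, residues=planted.mature))
        registry.planted_mirnas.append(planted)
        annotations.append((planted.precursor, "miRNA_precursor"))

    for k in range(1, cfg.n_novel_mirnas + 1):
        planted = _plant_hairpin(rng, genome, cfg, f"novel-{k}", "novel",
                                 None, known_matures, star_planted=(k % 2 == 0))
        registry.planted_mirnas.append(planted)

    for cls in DECOY_CLASSES:
        for k in range(1, cfg.n_decoy_hairpins + 1):
            planted = _plant_hairpin(rng, genome, cfg, f"decoy-{cls}-{k}",
                                     "decoy", cls, known_matures,
                                     star_planted=False)
            registry.planted_mirnas.append(planted)

    built = sum(len(s) for s in genome)
    if built > cfg.genome_length:
        raise ValueError(
            f"genome_length {cfg.genome_length} too short: need >= {built} nt "
            "to host the requested hairpins without overlap")
    genome.append(_random_seq(rng, cfg.genome_length - built, 0.45))
    genome_seq = "".join(genome)
    genome_rec = SequenceRecord(id="chr1", residues=genome_seq)

    ref = Reference(genome=genome_rec, annotations=annotations,
                    references=references, known_catalog=known_catalog,
                    registry=registry)
    _select_noise_species(rng, ref, cfg)
    return ref


def _select_noise_species(rng: np.random.Generator, ref: Reference,
                          cfg: SimulationConfig) -> None:
    """Background species: structural-RNA fragments plus screened intergenic
    24-mers whose windows cannot form a qualifying hairpin."""
    frag_pool: list[str] = []
    cats = list(ref.references)
    for _ in range(cfg.n_noise_fragments):
        cat = cats[rng.integers(len(cats))]
        gene = ref.references[cat][rng.integers(len(ref.references[cat]))]
        L = _noise_length(rng, cfg)
        if len(gene.residues) <= L:
            continue
        s = int(rng.integers(0, len(gene.residues) - L))
        frag_pool.append(gene.residues[s:s + L])
    ref.noise_fragments = sorted(set(frag_pool))

    precursors = [m.precursor for m in ref.registry.planted_mirnas]
    genic = [iv for iv, f in ref.annotations]
    g = ref.genome.residues
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < cfg.n_noise_intergenic and attempts < cfg.n_noise_intergenic * 30:
        attempts += 1
        s = int(rng.integers(0, len(g) - 24))
        iv = GenomicInterval("chr1", s, s + 24, "+")
        if any(iv.overlaps(p) for p in precursors) or any(iv.overlaps(x) for x in genic):
            continue
        seq = g[s:s + 24]
        if "N" in seq or seq in chosen:
            continue
        # screen: the window around this locus must not yield a passing
        # candidate even with arbitrary read support
        cand = hp.build_candidate(iv, ref.genome, seq)
        if cand is not None:
            v = hp.apply_novel_criteria(cand, np.array([100, 100, 100]))
            if v["fold_back"] and v["mfei_or_star"]:
                continue
        chosen.append(seq)
    # coding-RNA fragments, so classification sees CDS-overlapping reads
    cds_ivs = [iv for iv, f in ref.annotations if f == "CDS"]
    n_cds = cfg.n_noise_intergenic // 4
    attempts = 0
    added = 0
    while added < n_cds and attempts < n_cds * 30 and cds_ivs:
        attempts += 1
        iv0 = cds_ivs[rng.integers(len(cds_ivs))]
        L = _noise_length(rng, cfg)
        if len(iv0) <= L:
            continue
        s = iv0.start + int(rng.integers(0, len(iv0) - L))
        seq = g[s:s + L]
        if seq in chosen:
            continue
        cand = hp.build_candidate(GenomicInterval("chr1", s, s + L, "+"),
                                  ref.genome, seq)
        if cand is not None:
            v = hp.apply_novel_criteria(cand, np.array([100, 100, 100]))
            if v["fold_back"] and v["mfei_or_star"]:
                continue
        chosen.append(seq)
        added += 1
    ref.noise_intergenic = chosen


def _noise_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    classes = list(cfg.size_class_mix)
    probs = np.array([cfg.size_class_mix[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    if cls == "other":
        return int(rng.integers(18, 31))
    return int(cls)


# ---------------------------------------------------------------------------
# Library simulation

def _draw_profile(rng: np.random.Generator, cfg: SimulationConfig,
                  differential: bool) -> np.ndarray:
    nlib = len(cfg.library_ids)
    base = float(np.exp(rng.normal(cfg.tpm_log_mean, cfg.tpm_log_sigma)))
    base = float(np.clip(base, *cfg.tpm_clip))
    if differential:
        fold = rng.uniform(3.0, 8.0)
        profile = np.full(nlib, base / fold)
        profile[rng.integers(nlib)] = base
        # optionally a second library at an intermediate level
        j = rng.integers(nlib)
        profile[j] = max(profile[j], base / rng.uniform(1.0, fold))
    else:
        profile = base * rng.uniform(0.88, 1.13, size=nlib)
    return profile


def simulate_libraries(ref: Reference, cfg: SimulationConfig) -> CountTable:
    """Multinomial read counts per library from intended TPM plus background.

    Per-library totals are exactly reads_per_library. Read-support decoys get
    fixed low counts outside the multinomial pool.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    reg = ref.registry
    nlib = len(cfg.library_ids)

    species: list[str] = []
    weights: list[np.ndarray] = []
    mature_row: dict[str, int] = {}
    for m in reg.planted_mirnas:
        if m.decoy_class == "read_support":
            if cfg.noise_fraction < 1.0:
                reg.fixed_counts[m.name] = [5, 3, 2][:nlib]
            continue
        differential = (m.category != "decoy"
                        and rng.random() < cfg.differential_fraction)
        profile = _draw_profile(rng, cfg, differential)
        reg.differential[m.name] = bool(differential)
        mature_row[m.name] = len(species)
        species.append(m.mature)
        weights.append(profile)
        if m.star_planted and m.star:
            species.append(m.star)
            weights.append(profile * 0.3)

    W = np.array(weights) if weights else np.zeros((0, nlib))
    if len(W):
        target = (1.0 - cfg.noise_fraction) * 1e6
        scale = target / W.sum(axis=0).mean() if W.sum() > 0 else 0.0
        W = W * scale
        for name, row in mature_row.items():
            reg.planted_tpm[name] = [float(x) for x in np.round(W[row], 4)]

    noise_species = list(ref.noise_fragments) + list(ref.noise_intergenic)
    noise_w = np.exp(rng.normal(0.0, 1.0, size=len(noise_species)))
    noise_total = np.full(nlib, 1e6) - (W.sum(axis=0) if len(W) else np.zeros(nlib))
    NW = np.outer(noise_w / noise_w.sum(), noise_total) if len(noise_species) else \
        np.zeros((0, nlib))

    all_species = species + noise_species
    all_w = np.vstack([W, NW]) if len(all_species) else np.zeros((0, nlib))

    table = CountTable(library_ids=list(cfg.library_ids))
    fixed_total = np.zeros(nlib, dtype=np.int64)
    for name, counts in reg.fixed_counts.items():
        fixed_total += np.asarray(counts, dtype=np.int64)
    counts_matrix = np.zeros((len(all_species), nlib), dtype=np.int64)
    for j in range(nlib):
        n = cfg.reads_per_library - int(fixed_total[j])
        p = all_w[:, j] / all_w[:, j].sum()
        counts_matrix[:, j] = rng.multinomial(n, p)
    for i, seq in enumerate(all_species):
        if counts_matrix[i].any():
            table.add(seq, counts_matrix[i])
    for name, counts in reg.fixed_counts.items():
        table.add(reg.by_name(name).mature, counts)
    table.clean_totals = np.full(nlib, cfg.reads_per_library, dtype=np.int64)
    return table


def simulate_profiles(n: int, cfg: SimulationConfig,
                      seed: int | None = None) -> tuple[CountTable, dict[str, bool]]:
    """Standalone expression-profile simulation: n planted miRNA profiles plus
    a background filler, multinomially sampled. Returns the count table and
    the per-id differential truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nlib = len(cfg.library_ids)
    ids = [f"mir{i + 1}" for i in range(n)]
    truth: dict[str, bool] = {}
    W = np.zeros((n + 1, nlib))
    for i, mid in enumerate(ids):
        differential = rng.random() < cfg.differential_fraction
        truth[mid] = bool(differential)
        W[i] = _draw_profile(rng, cfg, differential)
    scale = 0.6 * 1e6 / W[:n].sum(axis=0).mean()
    W[:n] *= scale
    W[n] = 1e6 - W[:n].sum(axis=0)  # background filler
    table = CountTable(library_ids=list(cfg.library_ids))
    mat = np.zeros((n + 1, nlib), dtype=np.int64)
    for j in range(nlib):
        mat[:, j] = rng.multinomial(cfg.reads_per_library, W[:, j] / W[:, j].sum())
    # sequences are synthetic ids here; the count table is keyed by id
    for i, mid in enumerate(ids):
        table.counts[mid] = mat[i]
    table.counts["background"] = mat[n]
    table.clean_totals = np.full(nlib, cfg.reads_per_library, dtype=np.int64)
    return table, truth


# ---------------------------------------------------------------------------
# Transcriptome with planted target sites

def _parse_pattern(pattern: str) -> list[tuple[str, int]]:
    if pattern == "perfect":
        return []
    edits = []
    for tok in pattern.split(","):
        kind, pos = tok.split("@")
        edits.append((kind, int(pos)))
    return edits


_MM_CHOICE = {  # a base that is neither complement nor wobble partner
    "A": "A", "C": "C", "G": "A", "T": "C",
}


def _intended_states(mirna: str, edits: list[tuple[str, int]]) -> list[str]:
    states = ["match"] * len(mirna)
    for kind, pos in edits:
        states[pos - 1] = "GU" if kind == "gu" else "mismatch"
    return states


def intended_rule_verdicts(mirna: str, edits: list[tuple[str, int]]) -> dict[str, bool]:
    """Combinatorial intent for rules 1-5 straight from the edit list, plus
    the energy rule evaluated on the intended pairing states."""
    states = _intended_states(mirna, edits)
    nm = [s != "match" for s in states]
    score = states.count("mismatch") + 0.5 * states.count("GU")
    run = max_run = 0
    for f in nm:
        run = run + 1 if f else 0
        max_run = max(max_run, run)
    seed12 = states[:12]
    energy = tg.duplex_energy(mirna, states)
    perfect = tg.perfect_duplex_energy(mirna)
    ratio = abs(energy) / abs(perfect) if perfect else 0.0
    return {
        "total_mismatch": score <= 4,
        "adjacent_run": max_run <= 2,
        "seed_adjacent": not any(nm[i] and nm[i + 1] for i in range(1, 11)),
        "cleavage_match": states[9] == "match" and states[10] == "match",
        "seed_mismatch": seed12.count("mismatch") + 0.5 * seed12.count("GU") <= 2.5,
        "energy_ratio": ratio >= 0.75,
    }


def _site_sequence(mirna: str, edits: list[tuple[str, int]],
                   rng: np.random.Generator) -> str:
    """Transcript-sense site: reverse complement of the miRNA with the
    requested per-position mismatches/wobbles injected."""
    L = len(mirna)
    site = list(revcomp(mirna))
    for kind, pos in edits:
        if not 1 <= pos <= L:
            raise ValueError(f"edit position {pos} outside miRNA length {L}")
        m = mirna[pos - 1]
        j = L - pos  # site index pairing miRNA position pos
        if kind == "gu":
            if m == "G":
                site[j] = "T"
            elif m == "T":
                site[j] = "G"
            else:
                raise ValueError(f"G:U edit impossible at position {pos} "
                                 f"(miRNA base {m})")
        else:
            site[j] = _MM_CHOICE[m]
    return "".join(site)


def simulate_transcriptome(ref: Reference, cfg: SimulationConfig) -> list[SequenceRecord]:
    """Transcripts with one planted site per requested duplex pattern.

    Patterns cycle over the planted pass miRNAs; G:U edits pick a miRNA with
    a suitable base at the requested position.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    reg = ref.registry
    donors = [m for m in reg.planted_mirnas
              if m.intended_pass or m.category == "known"]
    if not donors:
        raise ValueError("no planted miRNAs to target")
    transcripts: list[SequenceRecord] = []
    for t in range(cfg.n_transcripts):
        L = int(rng.integers(800, 1500))
        transcripts.append(SequenceRecord(id=f"tx{t + 1}",
                                          residues=_random_seq(rng, L, 0.5)))
    d_idx = 0
    for p_i, pattern in enumerate(cfg.site_rule_profile):
        edits = _parse_pattern(pattern)
        donor = None
        for probe in range(len(donors)):
            cand = donors[(d_idx + probe) % len(donors)]
            ok = all(kind != "gu" or cand.mature[pos - 1] in "GT"
                     for kind, pos in edits)
            if ok and all(pos <= len(cand.mature) for _, pos in edits):
                donor = cand
                d_idx = (d_idx + probe + 1) % len(donors)
                break
        if donor is None:
            raise ValueError(f"no planted miRNA supports pattern {pattern!r}")
        site = _site_sequence(donor.mature, edits, rng)
        tx = transcripts[p_i % cfg.n_transcripts]
        pos = int(rng.integers(100, len(tx.residues) - len(site) - 100))
        new_res = tx.residues[:pos] + site + tx.residues[pos + len(site):]
        transcripts[p_i % cfg.n_transcripts] = SequenceRecord(
            id=tx.id, residues=new_res)
        verdicts = intended_rule_verdicts(donor.mature, edits)
        reg.planted_sites.append(PlantedSite(
            mirna=donor.name, transcript=tx.id, span=(pos, pos + len(site)),
            pattern=pattern, intended_verdicts=verdicts,
            expect_pass=all(verdicts.values()),
            cleavage_position=pos + len(site) - 10,
        ))
    ref.transcripts = transcripts
    _plant_anti_profiles(ref, cfg)
    return transcripts


def _plant_anti_profiles(ref: Reference, cfg: SimulationConfig) -> None:
    """Record which (miRNA, transcript) pairs are planted with anti-correlated
    expression; profiles themselves are derived in transcript_expression."""
    reg = ref.registry
    for site in reg.planted_sites:
        if site.expect_pass and reg.differential.get(site.mirna):
            reg.anti_pairs.append((site.mirna, site.transcript))


def transcript_expression(ref: Reference, cfg: SimulationConfig) -> pd.DataFrame:
    """Noise-free target-transcript abundance matrix: anti-pair transcripts
    mirror their miRNA's intended profile flipped, others are flat."""
    reg = ref.registry
    rng = np.random.default_rng(cfg.seed + 3)
    rows = {}
    anti_tx = {tx: mir for mir, tx in reg.anti_pairs}
    for tx in ref.transcripts:
        if tx.id in anti_tx:
            prof = np.array(reg.planted_tpm[anti_tx[tx.id]])
            flipped = prof.max() + prof.min() - prof
            rows[tx.id] = flipped / flipped.max()
        else:
            rows[tx.id] = np.full(len(cfg.library_ids),
                                  rng.uniform(0.8, 1.0))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(cfg.library_ids))


# ---------------------------------------------------------------------------
# Degradome

def simulate_degradome(ref: Reference, cfg: SimulationConfig,
                       seed: int | None = None) -> pd.DataFrame:
    """5'-end degradome tags: for each transcript carrying a pass-intended
    site, signal_fraction of its tags sit exactly at the canonical slice;
    the remainder (and all tags of siteless transcripts) are uniform."""
    rng = np.random.default_rng(cfg.seed + 4 if seed is None else seed)
    reg = ref.registry
    slice_by_tx: dict[str, int] = {}
    for site in reg.planted_sites:
        if site.expect_pass and site.transcript not in slice_by_tx:
            slice_by_tx[site.transcript] = site.cleavage_position
    records: dict[tuple[str, int], int] = {}
    for tx in ref.transcripts:
        T = cfg.degradome_tags_per_transcript
        L = len(tx.residues)
        n_signal = 0
        if tx.id in slice_by_tx and cfg.degradome_signal_fraction > 0:
            n_signal = int(rng.binomial(T, cfg.degradome_signal_fraction))
            key = (tx.id, slice_by_tx[tx.id])
            records[key] = records.get(key, 0) + n_signal
        for pos in rng.integers(0, L, size=T - n_signal):
            key = (tx.id, int(pos))
            records[key] = records.get(key, 0) + 1
    df = pd.DataFrame(
        [(tx, pos, c) for (tx, pos), c in sorted(records.items())],
        columns=["transcript", "position", "count"],
    )
    return df


# ---------------------------------------------------------------------------
# Degradome calibration (type-I error / power of the confirmation test)

def degradome_calibration(n_sites: int, signal_fraction: float,
                          tags_per_site: int = 200, transcript_length: int = 1000,
                          seed: int = 0, alpha: float = 0.05) -> float:
    """Empirical confirmation rate of the binomial slice test over simulated
    sites with the given true signal fraction (0 = uniform null)."""
    rng = np.random.default_rng(seed)
    mirna = "T" * 21  # placeholder; geometry only
    confirmed = 0
    for i in range(n_sites):
        slice_pos = int(rng.integers(20, transcript_length - 20))
        n_signal = int(rng.binomial(tags_per_site, signal_fraction)) \
            if signal_fraction > 0 else 0
        positions = list(rng.integers(0, transcript_length,
                                      size=tags_per_site - n_signal))
        positions += [slice_pos] * n_signal
        tags = pd.DataFrame({"transcript": "tx", "position": positions,
                             "count": 1})
        site = tg.TargetSite(
            mirna_id="m", transcript_id="tx",
            span=(slice_pos - 11, slice_pos - 11 + 21),
            alignment=tg.align_duplex(mirna, revcomp(mirna)),
            rule_verdicts={}, cleavage_position=slice_pos,
        )
        ev = tg.degradome_confirm(site, tags, transcript_length, alpha=alpha)
        confirmed += int(ev.confirmed)
    return confirmed / n_sites


# ---------------------------------------------------------------------------
# On-disk emission

def write_reference(ref: Reference, cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write genome/reference FASTAs, annotations, transcriptome, registry."""
    from .io import write_gff3
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta([ref.genome], paths["genome"])
    for cat, recs in ref.references.items():
        paths[cat] = outdir / f"{cat}.fa"
        write_fasta(recs, paths[cat])
    paths["known_mirnas"] = outdir / "known_mirnas.fa"
    write_fasta(ref.known_catalog, paths["known_mirnas"])
    paths["annotations"] = outdir / "annotations.gff3"
    write_gff3([(iv, f, f"ID={f}_{i}") for i, (iv, f) in enumerate(ref.annotations)],
               paths["annotations"])
    if ref.transcripts:
        paths["transcripts"] = outdir / "transcripts.fa"
        write_fasta(ref.transcripts, paths["transcripts"])
    paths["registry"] = outdir / "registry.json"
    ref.registry.to_json(paths["registry"])
    return paths
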