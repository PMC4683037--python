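"""End-to-end pipeline: simulate -> annotate -> discover -> express ->
targets -> report.

Each stage reads its inputs from, and writes its outputs to, a run directory,
so a run can resume from on-disk intermediates; with a fixed config and seed
all TSV outputs are byte-reproducible. A JSON manifest records the config
hash, per-stage record counts and timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import expression as ex
from . import hairpin as hp
from . import simulate as sim
from . import targets as tg
from .io import (CountTable, read_annotations, read_count_tsv, read_fasta,
                 write_fasta, write_results_tsv, SequenceRecord)

# Stage parameter defaults: the analysis thresholds the whole pipeline runs at.
DEFAULTS = {
    "min_len": ann.LENGTH_RANGE[0],
    "max_len": ann.LENGTH_RANGE[1],
    "max_mirna_mismatches": ann.MAX_MIRNA_MISMATCHES,
    "flank": hp.DEFAULT_FLANK,
    "mfei_threshold": hp.MFEI_THRESHOLD,
    "min_reads": hp.MIN_READS,
    "mature_length_min": hp.MATURE_LENGTH_RANGE[0],
    "mature_length_max": hp.MATURE_LENGTH_RANGE[1],
    "min_precursor_length": hp.MIN_PRECURSOR_LENGTH,
    "detection_tpm": ex.DETECTION_TPM,
    "differential_cutoff": ex.DIFFERENTIAL_CUTOFF,
    "log2_pseudocount": ex.LOG2_PSEUDOCOUNT,
    "fold_threshold": 2.0,
    "corr_threshold": -0.5,
    "max_total_mismatch": tg.MAX_TOTAL_MISMATCH,
    "max_adjacent_run": tg.MAX_ADJACENT_RUN,
    "max_seed_mismatch": tg.MAX_SEED_MISMATCH,
    "min_energy_ratio": tg.MIN_ENERGY_RATIO,
    "degradome_alpha": tg.DEGRADOME_ALPHA,
    # second rule-scorer preset for the method-overlap comparison
    "strict_total_mismatch": 3.0,
    "strict_energy_ratio": 0.85,
}

STAGES = ("simulate", "annotate", "discover", "express", "targets", "report")


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 1
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    parameters: dict = field(default_factory=lambda: dict(DEFAULTS))

    def __post_init__(self):
        unknown = set(self.parameters) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.parameters)
        self.parameters = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {"outdir", "seed", "simulation", "parameters"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_doc = doc.get("simulation", {})
        sim_fields = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
        unknown = set(sim_doc) - sim_fields
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("loop_length_range", "gc_target_range", "tpm_clip",
                    "library_ids", "site_rule_profile"):
            if key in sim_doc and isinstance(sim_doc[key], list):
                sim_doc[key] = tuple(sim_doc[key])
        return cls(
            outdir=doc.get("outdir", "run"),
            seed=int(doc.get("seed", 1)),
            simulation=sim.SimulationConfig(**sim_doc),
            parameters=doc.get("parameters", {}),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulation": _jsonable(dataclasses.asdict(self.simulation)),
            "parameters": self.parameters,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def config_hash(self) -> str:
        doc = json.dumps({
            "seed": self.seed,
            "simulation": _jsonable(dataclasses.asdict(self.simulation)),
            "parameters": self.parameters,
        }, sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


class StageError(RuntimeError):
    """A stage is missing one of its inputs."""


def _require(stage: str, *paths: Path) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise StageError(
            f"stage '{stage}' is missing required input(s): {', '.join(missing)}; "
            "run the earlier stages first")


def _outputs_exist(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: PipelineConfig, resume: bool = False) -> dict:
    out = Path(cfg.outdir) / "sim"
    outputs = [out / "genome.fa", out / "counts.tsv", out / "clean_totals.tsv",
               out / "transcripts.fa", out / "degradome.tsv",
               out / "transcript_expression.tsv", out / "registry.json"]
    if resume and _outputs_exist(outputs):
        return {"skipped": True}
    scfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    ref = sim.generate_reference(scfg)
    table = sim.simulate_libraries(ref, scfg)
    sim.simulate_transcriptome(ref, scfg)
    tx_expr = sim.transcript_expression(ref, scfg)
    degradome = sim.simulate_degradome(ref, scfg)
    sim.write_reference(ref, scfg, out)
    df = table.to_frame().reset_index()
    df.to_csv(out / "counts.tsv", sep="\t", index=False)
    pd.DataFrame({"library": table.library_ids,
                  "clean_total": table.clean_totals}).to_csv(
        out / "clean_totals.tsv", sep="\t", index=False)
    tx_expr.rename_axis("transcript").reset_index().to_csv(
        out / "transcript_expression.tsv", sep="\t", index=False)
    degradome.to_csv(out / "degradome.tsv", sep="\t", index=False)
    return {"reads": int(table.total_counts().sum()),
            "unique": table.n_unique(),
            "planted": len(ref.registry.planted_mirnas),
            "transcripts": len(ref.transcripts)}


def _load_counts(cfg: PipelineConfig) -> CountTable:
    out = Path(cfg.outdir) / "sim"
    totals = pd.read_csv(out / "clean_totals.tsv", sep="\t")
    return read_count_tsv(out / "counts.tsv",
                          clean_totals=dict(zip(totals["library"],
                                                totals["clean_total"])))


def stage_annotate(cfg: PipelineConfig, resume: bool = False) -> dict:
    out = Path(cfg.outdir) / "annotate"
    simdir = Path(cfg.outdir) / "sim"
    outputs = [out / "annotated_reads.tsv", out / "summary.tsv"]
    if resume and _outputs_exist(outputs):
        return {"skipped": True}
    _require("annotate", simdir / "counts.tsv", simdir / "genome.fa",
             simdir / "known_mirnas.fa", simdir / "annotations.gff3")
    out.mkdir(parents=True, exist_ok=True)
    table = _load_counts(cfg)
    genome = read_fasta(simdir / "genome.fa")[0]
    references = {cat: read_fasta(simdir / f"{cat}.fa")
                  for cat in ("rRNA", "tRNA", "snoRNA", "snRNA")}
    known = read_fasta(simdir / "known_mirnas.fa")
    annotations = read_annotations(simdir / "annotations.gff3")

    p = cfg.parameters
    filtered = ann.length_filter(table, p["min_len"], p["max_len"])
    hits = ann.map_exact(filtered, genome)
    annotated = ann.classify(filtered, hits, references, known, annotations)
    summary = ann.summarize(annotated, filtered)

    rows = []
    for a in annotated:
        rows.append({
            "sequence": a.sequence, "category": a.category,
            "cds_overlap": a.cds_overlap,
            "hits": ";".join(f"{h.start}-{h.end}:{h.strand}" for h in a.hits),
            **{lib: int(c) for lib, c in zip(filtered.library_ids, a.counts)},
        })
    write_results_tsv(pd.DataFrame(rows), out / "annotated_reads.tsv")
    write_results_tsv(summary, out / "summary.tsv")
    return {"filtered_unique": filtered.n_unique(),
            "mapped_unique": len(annotated)}


def stage_discover(cfg: PipelineConfig, resume: bool = False) -> dict:
    out = Path(cfg.outdir) / "discover"
    outputs = [out / "catalog.tsv", out / "precursors.fa", out / "structures.txt"]
    if resume and _outputs_exist(outputs):
        return {"skipped": True}
    anndir = Path(cfg.outdir) / "annotate"
    simdir = Path(cfg.outdir) / "sim"
    _require("discover", anndir / "annotated_reads.tsv", simdir / "genome.fa")
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(simdir / "genome.fa")[0]
    reads = pd.read_csv(anndir / "annotated_reads.tsv", sep="\t")
    libs = [c for c in reads.columns
            if c not in ("sequence", "category", "cds_overlap", "hits")]

    def parse_hits(s):
        from .io import GenomicInterval
        if not isinstance(s, str) or not s:
            return []
        out_ = []
        for tok in s.split(";"):
            span, strand = tok.rsplit(":", 1)
            a, b = span.split("-")
            out_.append(GenomicInterval(genome.id, int(a), int(b), strand))
        return out_

    others = reads[(reads["category"] == "other") & (~reads["cds_overlap"])]
    read_hits = {r["sequence"]: parse_hits(r["hits"]) for _, r in others.iterrows()}
    counts = {r["sequence"]: np.array([r[l] for l in libs], dtype=np.int64)
              for _, r in reads.iterrows()}
    candidates = hp.discover(read_hits, counts, genome,
                             read_set=set(reads["sequence"]),
                             flank=cfg.parameters["flank"])
    kept = hp.suppress_star_candidates(candidates)
    catalog = hp.name_and_merge([c for c in kept if c.passes])

    rows, fasta, structs = [], [], []
    for mir in catalog:
        for prec in mir.precursors:
            rows.append({
                "name": prec.mature.id, "mirna": mir.name,
                "mature": mir.mature.residues,
                "chrom": prec.window.chrom, "start": prec.window.start,
                "end": prec.window.end, "strand": prec.window.strand,
                "arm": prec.arm, "precursor_length": prec.length,
                "gc_percent": round(prec.gc, 2), "mfe": prec.structure.mfe,
                "amfe": round(prec.amfe, 2), "mfei": round(prec.mfei, 3),
                "star_observed": prec.star_observed,
                **{f"criterion_{k}": v for k, v in prec.verdicts.items()},
                **{f"reads_{lib}": int(c)
                   for lib, c in zip(libs, prec.support)},
            })
            fasta.append(SequenceRecord(id=prec.mature.id, residues=prec.sequence))
            structs.append((prec.mature.id, prec.sequence,
                            prec.structure.dotbracket, prec.structure.mfe))
    write_results_tsv(pd.DataFrame(rows), out / "catalog.tsv")
    write_fasta(fasta, out / "precursors.fa")
    with open(out / "structures.txt", "w") as fh:
        for name, seq, db, mfe in structs:
            fh.write(f">{name}\n{seq}\n{db} ({mfe})\n")
    return {"candidates": len(candidates), "novel_mirnas": len(catalog),
            "precursors": len(rows)}


def stage_express(cfg: PipelineConfig, resume: bool = False) -> dict:
    out = Path(cfg.outdir) / "express"
    outputs = [out / "tpm.tsv", out / "differential.tsv"]
    if resume and _outputs_exist(outputs):
        return {"skipped": True}
    disdir = Path(cfg.outdir) / "discover"
    anndir = Path(cfg.outdir) / "annotate"
    simdir = Path(cfg.outdir) / "sim"
    _require("express", disdir / "catalog.tsv", anndir / "annotated_reads.tsv",
             simdir / "known_mirnas.fa")
    out.mkdir(parents=True, exist_ok=True)
    catalog = pd.read_csv(disdir / "catalog.tsv", sep="\t")
    reads = pd.read_csv(anndir / "annotated_reads.tsv", sep="\t")
    table = _load_counts(cfg)
    libs = table.library_ids

    # expression rows: novel catalog matures plus known-miRNA reads; known
    # reads matching a catalog mature exactly carry its name, variants get a
    # derived id
    seq_to_name: dict[str, str] = {}
    if len(catalog):
        for _, r in catalog.drop_duplicates("mirna").iterrows():
            seq_to_name[r["mature"]] = r["mirna"]
    known_catalog = {rec.residues: rec.id
                     for rec in read_fasta(simdir / "known_mirnas.fa")}
    known = reads[reads["category"] == "known_miRNA"]
    for k, (_, r) in enumerate(known.iterrows(), 1):
        name = known_catalog.get(r["sequence"], f"known-variant-{k}")
        seq_to_name.setdefault(r["sequence"], name)

    sub = CountTable(library_ids=list(libs), clean_totals=table.clean_totals)
    for seq, name in seq_to_name.items():
        if seq in table.counts:
            sub.counts[name] = table.counts[seq]
    tpm = ex.compute_tpm(sub).sort_index()
    log2 = ex.log2_matrix(tpm, cfg.parameters["log2_pseudocount"])
    calls = ex.call_differential(tpm, cfg.parameters["detection_tpm"],
                                 cfg.parameters["differential_cutoff"])
    write_results_tsv(tpm.rename_axis("id").reset_index(), out / "tpm.tsv")
    write_results_tsv(log2.rename_axis("id").reset_index(), out / "log2_tpm.tsv")
    write_results_tsv(calls.rename_axis("id").reset_index(),
                      out / "differential.tsv")
    if tpm.shape[0] >= 2 and tpm.shape[1] >= 2:
        proj = ex.cluster_and_project(log2)
        write_results_tsv(
            proj["pca_coordinates"].rename_axis("library").reset_index(),
            out / "pca.tsv")
    n_diff = int(calls["is_differential"].sum()) if len(calls) else 0
    return {"expressed": int(tpm.shape[0]), "differential": n_diff}


def stage_targets(cfg: PipelineConfig, resume: bool = False) -> dict:
    out = Path(cfg.outdir) / "targets"
    outputs = [out / "sites.tsv", out / "venn.tsv", out / "pairs.tsv"]
    if resume and _outputs_exist(outputs):
        return {"skipped": True}
    simdir = Path(cfg.outdir) / "sim"
    disdir = Path(cfg.outdir) / "discover"
    exdir = Path(cfg.outdir) / "express"
    _require("targets", simdir / "transcripts.fa", disdir / "catalog.tsv",
             simdir / "degradome.tsv", exdir / "tpm.tsv")
    out.mkdir(parents=True, exist_ok=True)
    transcripts = read_fasta(simdir / "transcripts.fa")
    tx_len = {t.id: len(t.residues) for t in transcripts}
    catalog = pd.read_csv(disdir / "catalog.tsv", sep="\t")
    known = read_fasta(simdir / "known_mirnas.fa")
    mirnas = list(known)
    if len(catalog):
        for _, r in catalog.drop_duplicates("mirna").iterrows():
            mirnas.append(SequenceRecord(id=r["mirna"], residues=r["mature"]))
    degradome = pd.read_csv(simdir / "degradome.tsv", sep="\t")
    p = cfg.parameters

    sites = tg.scan_transcripts(mirnas, transcripts, method="rule_scorer")
    strict = tg.scan_transcripts(
        mirnas, transcripts, method="rule_strict",
        min_energy_ratio=p["strict_energy_ratio"],
        max_total_mismatch=p["strict_total_mismatch"])
    rows = []
    confirmed_keys = set()
    for site in sites:
        ev = tg.degradome_confirm(site, degradome, tx_len[site.transcript_id],
                                  alpha=p["degradome_alpha"])
        if ev.confirmed:
            confirmed_keys.add(site.key)
        rows.append({
            "mirna": site.mirna_id, "transcript": site.transcript_id,
            "start": site.span[0], "end": site.span[1],
            "mismatch_score": site.alignment.mismatch_score,
            "energy_ratio": round(site.alignment.energy_ratio, 4),
            **{f"rule_{k}": v for k, v in site.rule_verdicts.items()},
            "cleavage_position": site.cleavage_position,
            "tags_at_slice": ev.tags_at_slice, "tags_total": ev.tags_total,
            "p_value": ev.p_value, "degradome_confirmed": ev.confirmed,
        })
    write_results_tsv(pd.DataFrame(rows), out / "sites.tsv")

    venn = tg.overlap_methods({
        "rule_scorer": {s.key for s in sites},
        "rule_strict": {s.key for s in strict},
        "degradome": confirmed_keys,
    })
    write_results_tsv(
        pd.DataFrame(sorted(venn.items()), columns=["methods", "pairs"]),
        out / "venn.tsv")

    tpm = pd.read_csv(exdir / "tpm.tsv", sep="\t").set_index("id")
    tx_expr = pd.read_csv(simdir / "transcript_expression.tsv",
                          sep="\t").set_index("transcript")
    pair_rows = []
    for site in sites:
        if site.mirna_id not in tpm.index or site.transcript_id not in tx_expr.index:
            continue
        mprof = tpm.loc[site.mirna_id].to_numpy(dtype=float)
        tprof = tx_expr.loc[site.transcript_id].to_numpy(dtype=float)
        r, flagged = ex.correlate_pairs(
            mprof, tprof, p["fold_threshold"], p["corr_threshold"])
        pair_rows.append({
            "mirna": site.mirna_id, "transcript": site.transcript_id,
            "correlation": round(r, 4), "inverse_pair": flagged,
        })
    write_results_tsv(
        pd.DataFrame(pair_rows).drop_duplicates(["mirna", "transcript"])
        if pair_rows else pd.DataFrame(columns=["mirna", "transcript",
                                                "correlation", "inverse_pair"]),
        out / "pairs.tsv")
    return {"sites": len(sites), "strict_sites": len(strict),
            "degradome_confirmed": len(confirmed_keys)}


def stage_report(cfg: PipelineConfig, resume: bool = False) -> dict:
    out = Path(cfg.outdir) / "report"
    outputs = [out / "classification_summary.tsv",
               out / "size_distribution.tsv", out / "first_base.tsv"]
    if resume and _outputs_exist(outputs):
        return {"skipped": True}
    anndir = Path(cfg.outdir) / "annotate"
    disdir = Path(cfg.outdir) / "discover"
    _require("report", anndir / "summary.tsv", disdir / "catalog.tsv")
    out.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(anndir / "summary.tsv", sep="\t", na_values=["NA"])
    table = _load_counts(cfg)
    libs = table.library_ids

    # prepend the raw-reads row (simulated reads are already clean)
    raw_rows = [
        {"row": "high quality raw reads", "library": lib,
         "reads": int(t), "reads_pct": None, "unique": None, "unique_pct": None}
        for lib, t in zip(libs, table.clean_totals)
    ]
    full = pd.DataFrame(raw_rows + summary.to_dict("records"),
                        columns=summary.columns)
    write_results_tsv(full, out / "classification_summary.tsv")

    size_rows = []
    for lib_i, lib in enumerate(libs):
        by_len: dict[int, int] = {}
        for seq, vec in table.counts.items():
            by_len[len(seq)] = by_len.get(len(seq), 0) + int(vec[lib_i])
        total = sum(by_len.values())
        for L in sorted(by_len):
            size_rows.append({
                "library": lib, "length": L, "reads": by_len[L],
                "fraction": round(by_len[L] / total, 4) if total else 0.0})
    write_results_tsv(pd.DataFrame(size_rows), out / "size_distribution.tsv")

    catalog = pd.read_csv(disdir / "catalog.tsv", sep="\t")
    fb_rows = []
    if len(catalog):
        uniq = catalog.drop_duplicates("mirna")
        for cls, sub in uniq.groupby(
                uniq["mature"].str.len().map(lambda L: "24nt" if L == 24 else "short")):
            bases = sub["mature"].str[0].str.replace("T", "U")
            for base, n in bases.value_counts().items():
                fb_rows.append({"length_class": cls, "first_base": base,
                                "mirnas": int(n),
                                "fraction": round(n / len(sub), 4)})
    write_results_tsv(
        pd.DataFrame(fb_rows) if fb_rows else
        pd.DataFrame(columns=["length_class", "first_base", "mirnas", "fraction"]),
        out / "first_base.tsv")
    return {"summary_rows": len(full)}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "annotate": stage_annotate,
    "discover": stage_discover, "express": stage_express,
    "targets": stage_targets, "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, resume: bool = False,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    previous = {}
    if (outdir / "manifest.json").exists():
        previous = json.loads((outdir / "manifest.json").read_text()).get("stages", {})
    manifest = {"config_hash": cfg.config_hash(), "stages": dict(previous)}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        result = _STAGE_FUNCS[stage](cfg, resume=resume)
        skipped = bool(result.get("skipped", False))
        counts = {k: v for k, v in result.items() if k != "skipped"}
        if skipped and stage in previous:
            counts = previous[stage].get("record_counts", counts)
        manifest["stages"][stage] = {
            "record_counts": counts,
            "skipped": skipped,
            "seconds": round(time.time() - t0, 2),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
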