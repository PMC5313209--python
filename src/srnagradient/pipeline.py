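"""End-to-end orchestration: clean -> annotate -> known -> novel -> targets
-> quantify, with plain-TSV intermediates so any stage can be rerun alone.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import novel as novel_mod
from .annotation import (CATEGORIES, DEFAULT_PRIORITY, ReferenceSet,
                         annotate_tags)
from .cleaning import CleaningConfig, CleaningReport, clean_library, merge_reports
from .conserved import ExpressionMatrix, VennSummary, build_expression, identify_known, venn
from .novel import HairpinCandidate, NovelCriteria, call_novel, nucleotide_bias
from .quantify import classify_trend_table, ddct_from_table
from .seqio import (GffFeature, TagCount, collapse_tags, read_fasta, read_fastq,
                    to_rna, write_fasta, write_gff3, write_tsv)
from .targets import TargetConfig, TargetHit, format_duplex, scan_transcripts
from .utils import pct_half_up

log = logging.getLogger("srnagradient")


@dataclass
class PipelineConfig:
    fastq: dict[str, str]  # library id -> FASTQ path
    mature: str
    genome: str
    transcripts: str
    references: dict[str, str] = field(default_factory=dict)  # category -> FASTA
    ct_table: str | None = None
    calibrator: str = "CK"
    out_dir: str = "srna_out"
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    novel_criteria: NovelCriteria = field(default_factory=NovelCriteria)
    targets: TargetConfig = field(default_factory=TargetConfig)
    trend_tolerance: float = 0.1
    fold_backend: str = "builtin"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for section, klass in (("cleaning", CleaningConfig),
                               ("novel_criteria", NovelCriteria),
                               ("targets", TargetConfig)):
            if section in raw and isinstance(raw[section], dict):
                raw[section] = klass(**raw[section])
        return cls(**raw)

    def validate(self) -> None:
        paths = [*self.fastq.values(), self.mature, self.genome, self.transcripts,
                 *self.references.values()]
        if self.ct_table:
            paths.append(self.ct_table)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class RunReport:
    """All tables a run produces; every cell recomputable from intermediates."""

    cleaning: CleaningReport
    length_distribution: pd.DataFrame
    annotation_summary: pd.DataFrame
    tag_categories: dict[str, str]
    expression: ExpressionMatrix
    known_venn: VennSummary
    novel_venn: VennSummary | None
    novel_candidates: list[HairpinCandidate]
    novel_bias: pd.DataFrame | None
    novel_first_u: float | None
    novel_lengths: pd.DataFrame | None
    target_hits: list[TargetHit]
    trend_table: pd.DataFrame
    qpcr: pd.DataFrame | None


def _length_distribution(tags: list[TagCount], libraries: list[str]) -> pd.DataFrame:
    lengths = sorted({len(t.tag) for t in tags})
    rows = []
    for L in lengths:
        row = {"length": L}
        for lib in libraries:
            row[lib] = sum(t.counts.get(lib, 0) for t in tags if len(t.tag) == L)
        rows.append(row)
    df = pd.DataFrame(rows)
    for lib in libraries:
        total = df[lib].sum()
        df[f"{lib}_pct"] = [pct_half_up(v, total) for v in df[lib]]
    return df


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute the full pipeline; deterministic for identical inputs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    libraries = list(cfg.fastq)

    # stage 1: cleaning
    clean_reads = {}
    reports = []
    for lib, path in cfg.fastq.items():
        reads, report = clean_library(read_fastq(path), cfg.cleaning, lib)
        clean_reads[lib] = reads
        reports.append(report)
        log.info("clean %s: %d reads in, %d clean", lib,
                 report.counts[lib]["total_reads"], len(reads))
    cleaning = merge_reports(reports)
    write_tsv(cleaning.to_dataframe(), out / "cleaning_report.tsv")

    # stage 2: collapse to tags, restrict to the 18-30 nt mapping window
    window = {
        lib: [r for r in reads
              if cfg.cleaning.min_insert_len <= len(r.insert) <= cfg.cleaning.max_insert_len]
        for lib, reads in clean_reads.items()
    }
    tags = collapse_tags(window)
    length_dist = _length_distribution(tags, libraries)
    write_tsv(length_dist, out / "length_distribution.tsv")
    log.info("collapse: %d unique tags", len(tags))

    # stage 3: annotation triage
    ref_sets = []
    for cls in DEFAULT_PRIORITY:
        if cls == "exon_mRNA":
            # sense-strand degradation fragments only; antisense matches
            # would wrongly absorb miRNAs whose target sites sit in mRNAs
            ref_sets.append(ReferenceSet("exon_mRNA", read_fasta(cfg.transcripts)))
        elif cls in cfg.references:
            ref_sets.append(ReferenceSet(cls, read_fasta(cfg.references[cls])))
    categories, summary = annotate_tags(tags, ref_sets)
    unannotated = [t for t in tags if categories[t.tag] == "unannotated"]
    log.info("annotate: %d tags unannotated", len(unannotated))

    # stage 4: known miRNAs
    mature = read_fasta(cfg.mature, rna_to_dna=True)
    hits = identify_known(unannotated, mature)
    hit_by_tag = {h.tag: h for h in hits}
    for t in tags:
        if t.tag in hit_by_tag:
            categories[t.tag] = "known_miRNA"
    hits_per_lib = {
        lib: [(hit_by_tag[t.tag], t.counts.get(lib, 0))
              for t in unannotated if t.tag in hit_by_tag and t.counts.get(lib, 0) > 0]
        for lib in libraries
    }
    expression = build_expression(hits_per_lib, cleaning)
    write_tsv(expression.counts.reset_index(names="family"), out / "known_counts.tsv")
    write_tsv(expression.tpm.reset_index(names="family"), out / "known_tpm.tsv")
    known_sets = {
        lib: {h.family for h, n in hits_per_lib[lib] if n > 0} for lib in libraries
    }
    known_venn = venn(known_sets)
    write_tsv(known_venn.to_dataframe(), out / "known_venn.tsv")
    # recompute shares now that known_miRNA tags are split from unannotated
    unique = {c: 0 for c in CATEGORIES}
    reads = {c: 0 for c in CATEGORIES}
    for t in tags:
        unique[categories[t.tag]] += 1
        reads[categories[t.tag]] += t.total
    n_u, n_r = sum(unique.values()), sum(reads.values())
    annotation_summary = pd.DataFrame({
        "category": list(CATEGORIES),
        "unique_tags": [unique[c] for c in CATEGORIES],
        "unique_pct": [pct_half_up(unique[c], n_u) for c in CATEGORIES],
        "total_reads": [reads[c] for c in CATEGORIES],
        "reads_pct": [pct_half_up(reads[c], n_r) for c in CATEGORIES],
    })
    write_tsv(annotation_summary, out / "annotation_summary.tsv")
    log.info("known: %d tag hits, %d families", len(hits), len(expression.counts))

    # stage 5: novel miRNA prediction
    remaining = [t for t in unannotated if t.tag not in hit_by_tag]
    genome = read_fasta(cfg.genome)
    candidates = call_novel(remaining, genome, cfg.novel_criteria,
                            fold_backend=cfg.fold_backend)
    novel_bias = novel_first_u = novel_lengths = None
    novel_venn = None
    if candidates:
        bias, first_u, lengths = nucleotide_bias([c.mature for c in candidates])
        novel_bias, novel_first_u, novel_lengths = bias, first_u, lengths
        write_tsv(bias, out / "novel_bias.tsv")
        write_tsv(lengths, out / "novel_lengths.tsv")
        write_fasta([(f"novel_mir_{i+1}", c.mature) for i, c in enumerate(candidates)],
                    out / "novel_mature.fasta")
        write_gff3([GffFeature(c.contig, c.start, c.end, c.strand,
                               feature_id=f"novel_mir_{i+1}",
                               attributes={"mfe": f"{c.fold.mfe:.2f}"})
                    for i, c in enumerate(candidates)], out / "novel_loci.gff3")
        tag_index = {t.tag: t for t in remaining}
        novel_sets = {}
        for lib in libraries:
            present = set()
            for c in candidates:
                tc = tag_index.get(c.mature.replace("U", "T"))
                if tc is not None and tc.counts.get(lib, 0) > 0:
                    present.add(c.mature)
            novel_sets[lib] = present
        novel_venn = venn(novel_sets)
    log.info("novel: %d candidate hairpins", len(candidates))

    # stage 6: target prediction for the identified known miRNAs
    transcripts = read_fasta(cfg.transcripts)
    hit_refs = sorted({h.reference_id for h in hits})
    target_hits: list[TargetHit] = []
    for rid in hit_refs:
        target_hits.extend(scan_transcripts(rid, to_rna(mature[rid]),
                                            transcripts, cfg.targets))
    target_rows = [{
        "mirna": h.mirna_id, "transcript": h.transcript_id,
        "start": h.start, "end": h.end, "score": h.verdict.score,
        **{f"rule{i}": getattr(h.verdict, f"rule{i}") for i in range(1, 7)},
        "mfe_duplex": h.verdict.mfe_duplex, "mfe_perfect": h.verdict.mfe_perfect,
        "mfe_ratio": round(h.verdict.mfe_ratio, 4),
        "duplex": format_duplex(h.alignment).replace("\n", " / "),
    } for h in target_hits]
    write_tsv(pd.DataFrame(target_rows), out / "target_hits.tsv")
    log.info("targets: %d passing sites", len(target_hits))

    # stage 7: expression analytics
    trend_table = classify_trend_table(expression.tpm, libraries, cfg.trend_tolerance)
    write_tsv(trend_table, out / "trend_table.tsv")
    qpcr = None
    if cfg.ct_table:
        ct = pd.read_csv(cfg.ct_table, sep="\t")
        qpcr = ddct_from_table(ct, cfg.calibrator)
        write_tsv(qpcr, out / "qpcr_results.tsv")

    summary_json = {
        "libraries": libraries,
        "clean_reads": {lib: cleaning.clean_reads(lib) for lib in libraries},
        "unique_tags": len(tags),
        "known_families": int(len(expression.counts)),
        "novel_candidates": len(candidates),
        "target_hits": len(target_hits),
    }
    (out / "run_summary.json").write_text(json.dumps(summary_json, indent=1))

    return RunReport(cleaning, length_dist, annotation_summary, categories,
                     expression, known_venn, novel_venn, candidates, novel_bias,
                     novel_first_u, novel_lengths, target_hits, trend_table, qpcr)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
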