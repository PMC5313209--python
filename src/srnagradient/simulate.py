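"""Ground-truth simulator for the whole pipeline.

Emulates a three-site small-RNA sequencing experiment at desk scale:
adapter-ligated reads with known per-category contamination proportions,
planted known-miRNA tags at chosen per-site abundances (including
monotone trends), textbook hairpin precursors embedded in a toy genome,
non-hairpin decoy loci, ncRNA/repeat reference sets with matching
fragment reads, transcripts carrying target sites of graded rule
compliance, and triplicate qPCR Ct tables with configurable fold changes.

Every category is constructed to be mutually exclusive (e.g. poly-A reads
have a findable 3' adapter and an insert >= 18 nt) and every planted
object is verified at generation time against its defining constraint
(precursors are folded and must pass the hairpin criteria; decoys must
fail; target-site labels are checked against the rule engine), so
downstream recall/precision can be scored exactly.  A single integer seed
drives one numpy Generator; equal seeds give byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import novel as novel_mod
from .annotation import ReferenceSet, match_tag
from .cleaning import CleaningConfig, find_adapter
from .conserved import identify_known
from .seqio import RawRead, TagCount, reverse_complement, to_rna, write_fasta, write_fastq
from .targets import align_window, evaluate_energy, score_duplex
from .thermo import fold

BASES = np.array(list("ACGT"))

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


@dataclass
class QpcrSpec:
    """True fold changes per gene and condition, and the Ct noise model."""

    genes: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "miR2119": {"CK": 1.0, "MD": 0.5, "SD": 0.25},
        "miR5559": {"CK": 1.0, "MD": 0.4, "SD": 0.2},
        "BI1": {"CK": 1.0, "MD": 2.0, "SD": 4.0},
        "HIRA": {"CK": 1.0, "MD": 2.5, "SD": 5.0},
    })
    calibrator: str = "CK"
    reference_gene: str = "U6"
    replicates: int = 3
    ct_sigma: float = 0.1
    reference_base_ct: float = 20.0
    base_delta_ct: float = 5.0


@dataclass
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Proportions are of high-quality reads and must sum to 1; the clean
    fraction is further split among planted miRNA/ncRNA/random sources.
    Scale is desk-sized (1e4 reads/library) rather than the >1e7 of a
    production run.
    """

    seed: int = 0
    libraries: tuple[str, ...] = ("HuL", "YuL", "DaB")
    n_reads: int = 10_000
    proportions: dict[str, float] = field(default_factory=lambda: {
        "clean": 0.90,
        "adapter3_null": 0.02,
        "insert_null": 0.02,
        "adapter5_contaminants": 0.02,
        "smaller_than_18nt": 0.02,
        "polyA": 0.02,
    })
    low_quality_fraction: float = 0.003
    read_length: int = 50
    # known miRNAs: name -> per-site relative abundance profile
    known_profiles: dict[str, tuple[int, int, int]] = field(default_factory=lambda: {
        "cko-miR2001": (4, 2, 1),    # monotone_down along the gradient
        "cko-miR2002": (1, 2, 4),    # monotone_up
        "cko-miR2003": (2, 2, 2),    # flat
        "cko-miR2004": (3, 0, 0),    # site-unique miRNAs for the Venn
        "cko-miR2005": (0, 3, 0),
        "cko-miR2006": (0, 0, 3),
        "cko-miR2007": (2, 2, 0),
        "cko-miR2008": (0, 2, 2),
    })
    known_scale: int = 40
    mature_len: int = 21
    n_extra_mature_refs: int = 4  # reference entries never planted in reads
    n_novel: int = 5
    novel_reads: int = 25
    n_decoys: int = 2
    decoy_reads: int = 10
    ncrna_per_class: int = 3
    ncrna_len: tuple[int, int] = (80, 200)
    ncrna_fragments: int = 5
    ncrna_fragment_reads: int = 8
    n_transcripts: int = 12
    transcript_len: int = 300
    transcript_fragment_reads: int = 8
    random_tag_count_range: tuple[int, int] = (5, 20)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    novel_criteria: novel_mod.NovelCriteria = field(default_factory=novel_mod.NovelCriteria)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        if len(self.libraries) != len(next(iter(self.known_profiles.values()))):
            raise ValueError("profile length != number of libraries")


@dataclass
class SimulatedRun:
    out_dir: Path
    fastq: dict[str, Path]
    genome: Path
    mature: Path
    references: dict[str, Path]
    transcripts: Path
    ct_table: Path
    truth_path: Path
    truth: dict


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


class _Maker:
    """Stateful helpers bound to one rng + config."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.ccfg = cfg.cleaning

    def rand_seq(self, length: int) -> str:
        return _rand_seq(self.rng, length)

    def make_read_seq(self, insert: str) -> str:
        seq = insert + self.ccfg.adapter3
        if len(seq) < self.cfg.read_length:
            seq += self.rand_seq(self.cfg.read_length - len(seq))
        return seq[:self.cfg.read_length]

    def insert_ok(self, insert: str) -> bool:
        """Constraints that make an insert unambiguously 'clean'."""
        if not self.ccfg.min_insert_len <= len(insert) <= self.ccfg.max_insert_len:
            return False
        if insert.count("A") / len(insert) >= self.ccfg.polya_fraction:
            return False
        if self.ccfg.adapter5 in insert:
            return False
        seq = self.make_read_seq(insert)
        return find_adapter(seq, self.ccfg.adapter3, self.ccfg.adapter_min_overlap,
                            self.ccfg.adapter_max_mismatch_rate) == len(insert)

    def clean_insert(self, length: int | None = None, tries: int = 200) -> str:
        for _ in range(tries):
            n = length or int(self.rng.integers(18, 31))
            insert = self.rand_seq(n)
            if self.insert_ok(insert):
                return insert
        raise RuntimeError("could not construct a clean insert")


def _plant_site(transcript: str, site: str, pos: int) -> str:
    return transcript[:pos] + site + transcript[pos + len(site):]


def _mm_site(mature_dna: str, positions_1based: tuple[int, ...]) -> str:
    """Perfect-complement site with same-base mismatches at given miRNA
    positions (a base facing itself is never WC nor G:U)."""
    site = list(reverse_complement(mature_dna))
    L = len(mature_dna)
    for p in positions_1based:
        site[L - p] = mature_dna[p - 1]
    return "".join(site)


def simulate_run(cfg: SimulationConfig, out_dir: str | os.PathLike) -> SimulatedRun:
    """Generate the full fixture set and its ground truth.

    Writes per-library FASTQ, genome/mature/ncRNA/transcript FASTA, a
    long-format Ct TSV and ground_truth.json into ``out_dir``; returns a
    SimulatedRun with the paths and the in-memory truth dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mk = _Maker(cfg)
    rng = mk.rng
    libs = list(cfg.libraries)

    # --- mature miRNA reference ---------------------------------------
    known: dict[str, str] = {}  # id -> mature DNA
    while len(known) < len(cfg.known_profiles):
        seq = mk.clean_insert(cfg.mature_len)
        if sum(seq.count(b) for b in "GT") < 5:
            continue
        if identify_known([TagCount(seq, {"x": 1})], known):
            continue  # too close to an already chosen mature
        name = list(cfg.known_profiles)[len(known)]
        known[name] = seq
    extra_refs = {}
    while len(extra_refs) < cfg.n_extra_mature_refs:
        seq = mk.clean_insert(cfg.mature_len)
        if identify_known([TagCount(seq, {"x": 1})], {**known, **extra_refs}):
            continue
        extra_refs[f"cko-miR3{len(extra_refs):03d}"] = seq
    mature_all = {**known, **extra_refs}

    # --- ncRNA / repeat reference sets --------------------------------
    refs: dict[str, dict[str, str]] = {}
    for cls in NCRNA_CLASSES:
        refs[cls] = {
            f"{cls}_{i}": mk.rand_seq(int(rng.integers(*cfg.ncrna_len)))
            for i in range(cfg.ncrna_per_class)
        }

    # --- transcripts with graded target sites -------------------------
    site_plan = []  # (mirna_id, transcript_idx, pos, label, mm positions)
    mirna_ids = list(known)
    site_plan.append((mirna_ids[0], 0, 100, "pass_all", ()))
    site_plan.append((mirna_ids[1], 1, 80, "pass_all", ()))
    site_plan.append((mirna_ids[0], 2, 120, "fail_rule4", (10,)))
    site_plan.append((mirna_ids[1], 3, 60, "fail_rule6", (13, 15, 17, 19)))

    def site_label_ok(mirna_dna: str, site: str, label: str) -> bool:
        aln = align_window(to_rna(mirna_dna), to_rna(site), allow_gap=False)
        verdict = score_duplex(aln)
        verdict = evaluate_energy(verdict, to_rna(mirna_dna), to_rna(site))
        if label == "pass_all":
            return verdict.all_pass
        if label == "fail_rule4":
            return (not verdict.rule4) and verdict.rule1 and verdict.rule2 \
                and verdict.rule3 and verdict.rule5 and verdict.rule6
        if label == "fail_rule6":
            return (not verdict.rule6) and verdict.rule1 and verdict.rule2 \
                and verdict.rule3 and verdict.rule4 and verdict.rule5
        raise ValueError(label)

    # re-draw the involved matures until every designed site carries its label
    for _ in range(500):
        ok = True
        for mid, _t, _p, label, mms in site_plan:
            site = _mm_site(known[mid], mms)
            if not site_label_ok(known[mid], site, label):
                ok = False
                seq = mk.clean_insert(cfg.mature_len)
                if not identify_known([TagCount(seq, {"x": 1})],
                                      {k: v for k, v in mature_all.items() if k != mid}):
                    known[mid] = seq
                    mature_all[mid] = seq
        if ok:
            break
    else:
        raise RuntimeError("could not satisfy target-site labels")

    transcripts = {
        f"unigene{i:03d}": mk.rand_seq(cfg.transcript_len)
        for i in range(cfg.n_transcripts)
    }
    truth_sites: dict[str, list[dict]] = {}
    for mid, t_idx, pos, label, mms in site_plan:
        t_id = f"unigene{t_idx:03d}"
        site = _mm_site(known[mid], mms)
        transcripts[t_id] = _plant_site(transcripts[t_id], site, pos)
        truth_sites.setdefault(t_id, []).append({
            "mirna": mid, "start": pos, "end": pos + len(site), "label": label,
        })

    # --- genome: textbook precursors + shuffled decoys -----------------
    crit = cfg.novel_criteria

    def ac_seq(n: int) -> str:
        return "".join(np.array(list("AC"))[rng.integers(0, 2, n)])

    def make_star(mature: str) -> str | None:
        """Reverse complement of the mature with two internal G:U wobbles.

        The wobbles keep every position paired but stop the mature tag
        from exact-matching the minus strand at the star arm.
        """
        star = list(reverse_complement(mature))
        L = len(mature)
        wobbled = 0
        for i in range(3, L - 3):
            if wobbled == 2:
                break
            if mature[i] == "G":
                star[L - 1 - i] = "T"  # G:U pair
                wobbled += 1
            elif mature[i] == "T":
                star[L - 1 - i] = "G"  # U:G pair
                wobbled += 1
        return "".join(star) if wobbled == 2 else None

    def make_precursor() -> tuple[str, str, int]:
        """(precursor-with-flanks, mature, mature offset in block)."""
        for _ in range(200):
            mature = mk.clean_insert(cfg.mature_len)
            if identify_known([TagCount(mature, {"x": 1})], mature_all):
                continue
            star = make_star(mature)
            if star is None:
                continue
            loop = ac_seq(8)
            hairpin = mature + loop + star
            left = ac_seq(crit.flank_up + 20)
            right = ac_seq(crit.flank_down + 20)
            block = left + hairpin + right
            offset = len(left)
            # verify exactly as call_novel will see it
            prec, _, _, off = novel_mod._excise(block, offset, offset + cfg.mature_len,
                                                "+", crit.flank_up, crit.flank_down)
            fr = fold(prec)
            flags, _, _ = novel_mod.evaluate_hairpin(fr, off, cfg.mature_len, crit)
            if all(flags.values()):
                return block, mature, offset
        raise RuntimeError("could not build a qualifying precursor")

    def make_decoy() -> tuple[str, str, int]:
        for _ in range(200):
            block = mk.rand_seq(60) + mk.rand_seq(150) + mk.rand_seq(60)
            start = 100
            tag = block[start:start + cfg.mature_len]
            if not mk.insert_ok(tag):
                continue
            if identify_known([TagCount(tag, {"x": 1})], mature_all):
                continue
            rejected = True
            for up, down in ((crit.flank_up, crit.flank_down),
                             (crit.flank_down, crit.flank_up)):
                for strand in "+-":
                    prec, _, _, off = novel_mod._excise(
                        block, start, start + cfg.mature_len, strand, up, down)
                    fr = fold(prec)
                    flags, _, _ = novel_mod.evaluate_hairpin(fr, off, cfg.mature_len, crit)
                    if all(flags.values()):
                        rejected = False
            if rejected:
                return block, tag, start
        raise RuntimeError("could not build a non-hairpin decoy")

    genome_parts: list[str] = []
    novel_truth: list[dict] = []
    decoy_truth: list[dict] = []
    cursor = 0
    for i in range(cfg.n_novel):
        block, mature, offset = make_precursor()
        novel_truth.append({
            "name": f"novel_mir_{i + 1}", "mature": mature,
            "contig": "chr1", "start": cursor + offset,
            "end": cursor + offset + len(mature), "strand": "+",
        })
        genome_parts.append(block)
        cursor += len(block)
    for i in range(cfg.n_decoys):
        block, tag, start = make_decoy()
        decoy_truth.append({"tag": tag, "contig": "chr1", "start": cursor + start})
        genome_parts.append(block)
        cursor += len(block)
    genome = {"chr1": "".join(genome_parts)}

    for entry in novel_truth:  # planted matures must be unique in the genome
        g = genome["chr1"]
        if g.count(entry["mature"]) != 1 or entry["mature"] in reverse_complement(g):
            raise RuntimeError("planted mature is not unique in the genome")

    # --- ncRNA fragments (verified to hit only their own class) --------
    ref_sets = [ReferenceSet(cls, refs[cls]) for cls in NCRNA_CLASSES]
    ref_sets.append(ReferenceSet("exon_mRNA", transcripts))
    fragments: dict[str, list[str]] = {}
    for cls in NCRNA_CLASSES + ("exon_mRNA",):
        pool = refs[cls] if cls != "exon_mRNA" else transcripts
        frags: list[str] = []
        guard = 0
        while len(frags) < cfg.ncrna_fragments:
            guard += 1
            if guard > 500:
                raise RuntimeError(f"cannot draw fragments for {cls}")
            src = list(pool.values())[int(rng.integers(0, len(pool)))]
            n = int(rng.integers(18, 31))
            if len(src) <= n:
                continue
            p = int(rng.integers(0, len(src) - n))
            frag = src[p:p + n]
            if not mk.insert_ok(frag) or frag in frags:
                continue
            first = next((rs.label for rs in ref_sets
                          if match_tag(frag, rs) is not None), None)
            if first != cls:
                continue
            if identify_known([TagCount(frag, {"x": 1})], mature_all):
                continue
            frags.append(frag)
        fragments[cls] = frags

    # --- per-library reads ---------------------------------------------
    categories = list(cfg.proportions)
    reads_per_lib: dict[str, list[RawRead]] = {}
    truth_cleaning: dict[str, dict] = {}
    truth_known_counts: dict[str, dict[str, int]] = {m: {} for m in known}

    for lib_idx, lib in enumerate(libs):
        n_low = int(rng.binomial(cfg.n_reads, cfg.low_quality_fraction))
        n_hq = cfg.n_reads - n_low
        cat_counts = {c: int(v) for c, v in zip(categories, rng.multinomial(
            n_hq, [cfg.proportions[c] for c in categories]))}
        n_clean = cat_counts["clean"]

        inserts: list[str] = []
        # planted known miRNAs
        for mid, profile in cfg.known_profiles.items():
            count = profile[lib_idx] * cfg.known_scale
            truth_known_counts[mid][lib] = count
            inserts.extend([known[mid]] * count)
        # planted novel matures and decoy tags
        for entry in novel_truth:
            inserts.extend([entry["mature"]] * cfg.novel_reads)
        for entry in decoy_truth:
            inserts.extend([entry["tag"]] * cfg.decoy_reads)
        # ncRNA / mRNA fragments
        for cls, frags in fragments.items():
            for frag in frags:
                inserts.extend([frag] * cfg.ncrna_fragment_reads)
        if len(inserts) > n_clean:
            raise ValueError("planted clean reads exceed the clean budget; "
                             "raise n_reads or the clean proportion")
        # random unannotated remainder
        lo, hi = cfg.random_tag_count_range
        while len(inserts) < n_clean:
            count = min(int(rng.integers(lo, hi + 1)), n_clean - len(inserts))
            tag = mk.clean_insert()
            if tag in genome["chr1"] or tag in reverse_complement(genome["chr1"]):
                continue
            if identify_known([TagCount(tag, {"x": 1})], mature_all):
                continue
            inserts.extend([tag] * count)

        seqs: list[tuple[str, str]] = [("clean", mk.make_read_seq(i)) for i in inserts]
        for _ in range(cat_counts["adapter3_null"]):
            while True:
                s = mk.rand_seq(cfg.read_length)
                if find_adapter(s, mk.ccfg.adapter3, mk.ccfg.adapter_min_overlap,
                                mk.ccfg.adapter_max_mismatch_rate) is None:
                    break
            seqs.append(("adapter3_null", s))
        for _ in range(cat_counts["insert_null"]):
            seqs.append(("insert_null", mk.make_read_seq("")))
        for _ in range(cat_counts["adapter5_contaminants"]):
            insert = mk.ccfg.adapter5 + mk.rand_seq(4)
            seqs.append(("adapter5_contaminants", mk.make_read_seq(insert)))
        for _ in range(cat_counts["smaller_than_18nt"]):
            while True:
                insert = mk.rand_seq(int(rng.integers(10, 18)))
                s = mk.make_read_seq(insert)
                if find_adapter(s, mk.ccfg.adapter3, mk.ccfg.adapter_min_overlap,
                                mk.ccfg.adapter_max_mismatch_rate) == len(insert):
                    break
            seqs.append(("smaller_than_18nt", s))
        for _ in range(cat_counts["polyA"]):
            seqs.append(("polyA", mk.make_read_seq("A" * int(rng.integers(18, 26)))))

        order = rng.permutation(len(seqs))
        reads = []
        for rank, idx in enumerate(order):
            _, s = seqs[idx]
            reads.append(RawRead(f"{lib}_r{rank:06d}", s, "I" * len(s)))
        for k in range(n_low):
            s = mk.rand_seq(cfg.read_length)
            reads.append(RawRead(f"{lib}_low{k:04d}", s, "#" * len(s)))
        reads_per_lib[lib] = reads
        truth_cleaning[lib] = {
            "total_reads": cfg.n_reads,
            "high_quality": n_hq,
            "categories": cat_counts,
        }

    # --- qPCR Ct table ---------------------------------------------------
    q = cfg.qpcr
    ct_rows = ["gene\tcondition\treplicate\tct\tis_reference"]
    conditions = list(next(iter(q.genes.values())))
    ref_cts = {
        cond: [q.reference_base_ct + rng.normal(0, q.ct_sigma)
               for _ in range(q.replicates)]
        for cond in conditions
    }
    for cond in conditions:
        for rep, ct in enumerate(ref_cts[cond], start=1):
            ct_rows.append(f"{q.reference_gene}\t{cond}\t{rep}\t{ct:.4f}\t1")
    for gene, folds in q.genes.items():
        for cond in conditions:
            dct = q.base_delta_ct - float(np.log2(folds[cond]))
            for rep in range(1, q.replicates + 1):
                ct = ref_cts[cond][rep - 1] + dct + rng.normal(0, q.ct_sigma)
                ct_rows.append(f"{gene}\t{cond}\t{rep}\t{ct:.4f}\t0")

    # --- write everything ------------------------------------------------
    fastq_paths = {}
    for lib in libs:
        path = out / f"{lib}.fastq"
        write_fastq(reads_per_lib[lib], path)
        fastq_paths[lib] = path
    genome_path = out / "genome.fasta"
    write_fasta(list(genome.items()), genome_path)
    mature_path = out / "mature_mirna.fasta"
    write_fasta([(mid, to_rna(seq)) for mid, seq in mature_all.items()], mature_path)
    ref_paths = {}
    for cls in NCRNA_CLASSES:
        p = out / f"{cls}.fasta"
        write_fasta(list(refs[cls].items()), p)
        ref_paths[cls] = p
    transcripts_path = out / "transcripts.fasta"
    write_fasta(list(transcripts.items()), transcripts_path)
    ct_path = out / "qpcr_ct.tsv"
    ct_path.write_text("\n".join(ct_rows) + "\n")

    known_sets = {
        lib: sorted({f"MIR{mid.split('miR')[1]}" for mid, prof in cfg.known_profiles.items()
                     if prof[libs.index(lib)] > 0})
        for lib in libs
    }
    trend_by_family = {}
    for mid, prof in cfg.known_profiles.items():
        fam = f"MIR{mid.split('miR')[1]}"
        if prof == (4, 2, 1):
            trend_by_family[fam] = "monotone_down"
        elif prof == (1, 2, 4):
            trend_by_family[fam] = "monotone_up"
        elif prof == (2, 2, 2):
            trend_by_family[fam] = "flat"

    truth = {
        "seed": cfg.seed,
        "libraries": libs,
        "cleaning": truth_cleaning,
        "known_mirnas": {mid: {"sequence": known[mid],
                               "family": f"MIR{mid.split('miR')[1]}",
                               "counts": truth_known_counts[mid]}
                         for mid in known},
        "known_sets": known_sets,
        "trends": trend_by_family,
        "novel": novel_truth,
        "decoys": decoy_truth,
        "target_sites": truth_sites,
        "qpcr": {"genes": q.genes, "calibrator": q.calibrator,
                 "sigma": q.ct_sigma, "replicates": q.replicates},
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return SimulatedRun(out, fastq_paths, genome_path, mature_path, ref_paths,
                        transcripts_path, ct_path, truth_path, truth)
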