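"""Novel miRNA prediction from genome-mapped, otherwise-unannotated tags.

Each unannotated tag is mapped exactly (both strands) to the genome; for
every locus a candidate precursor window is excised on both arm
orientations (short flank on one side, long on the other), folded, and
kept only if the hairpin satisfies the full criteria set: strong MFE, a
single terminal loop, the mapped tag (the putative mature) lying wholly
within one arm with enough of it paired, a recoverable star partner with
the canonical 2-nt 3' overhang, and bounded duplex asymmetry.

The positional nucleotide-bias report (5' U preference etc.) and the
length histogram of the accepted mature sequences are computed here too.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqio import TagCount, reverse_complement, to_dna, to_rna
from .thermo import FoldResult, fold
from .utils import pct_half_up

_TERMINAL_LOOP = re.compile(r"\(\.*\)")


@dataclass
class NovelCriteria:
    """Hairpin acceptance thresholds (all exposed, none hidden).

    flank_up/flank_down are the excision window sizes tried on both arm
    orientations; mfe_max is the most permissive precursor free energy in
    kcal/mol; the remaining fields bound the mature/star duplex geometry.
    """

    flank_up: int = 20
    flank_down: int = 160
    mfe_max: float = -18.0
    mature_len_min: int = 18
    mature_len_max: int = 26
    max_mature_star_mismatch: int = 4
    max_asymmetry: int = 4
    min_paired_in_mature: int = 14

    def __post_init__(self) -> None:
        if self.mature_len_min > self.mature_len_max:
            raise ValueError("mature_len_min > mature_len_max")
        if self.mfe_max > 0:
            raise ValueError("mfe_max must be <= 0")


@dataclass
class HairpinCandidate:
    contig: str
    start: int  # precursor locus, 0-based half-open, genomic
    end: int
    strand: str
    precursor: str  # RNA, transcript orientation
    fold: FoldResult
    mature: str  # RNA
    mature_offset: int  # within precursor
    arm: str  # "5p" or "3p"
    star_offset: tuple[int, int]  # within precursor, half-open
    flags: dict[str, bool] = field(default_factory=dict)
    supporting_reads: int = 0

    @property
    def passed(self) -> bool:
        return all(self.flags.values())


def evaluate_hairpin(fr: FoldResult, mature_offset: int, mature_len: int,
                     criteria: NovelCriteria) -> tuple[dict[str, bool], str, tuple[int, int]]:
    """Score one folded precursor against the criteria.

    Returns (flags, arm, star interval).  All flags are computed even when
    an early one fails, so a candidate can be audited.
    """
    flags: dict[str, bool] = {}
    structure = fr.structure
    m_lo, m_hi = mature_offset, mature_offset + mature_len

    flags["mfe"] = fr.mfe <= criteria.mfe_max
    flags["mature_length"] = criteria.mature_len_min <= mature_len <= criteria.mature_len_max

    loops = list(_TERMINAL_LOOP.finditer(structure))
    flags["single_hairpin"] = len(loops) == 1

    arm = "5p"
    star: tuple[int, int] = (0, 0)
    if loops:
        loop = loops[0]
        loop_lo, loop_hi = loop.start(), loop.end()  # includes closing pair
        on_5p = m_hi <= loop_lo + 1
        on_3p = m_lo >= loop_hi - 1
        flags["mature_in_one_arm"] = on_5p or on_3p
        arm = "5p" if on_5p else "3p"
    else:
        flags["mature_in_one_arm"] = False

    pt = fr.pair_table()
    paired = [i for i in range(m_lo, m_hi) if pt[i] != -1]
    n_paired = len(paired)
    flags["paired_in_mature"] = n_paired >= criteria.min_paired_in_mature
    flags["mature_star_mismatch"] = (mature_len - n_paired) <= criteria.max_mature_star_mismatch

    if n_paired >= 2:
        j1, j2 = paired[0], paired[-1]
        partners = (pt[j1], pt[j2])
        star_lo, star_hi = min(partners), max(partners) + 1
        # canonical Dicer product: the star's 3' end overhangs by 2 nt
        if arm == "5p":
            star_hi = min(star_hi + 2, len(structure))
        else:
            star_lo = max(star_lo - 2, 0)
        star = (star_lo, star_hi)
        # asymmetry compares the paired mature span against the star span
        # (before the 2-nt overhang extension)
        flags["asymmetry"] = abs((j2 - j1 + 1) - (max(partners) - min(partners) + 1)) \
            <= criteria.max_asymmetry
    else:
        flags["asymmetry"] = False
    return flags, arm, star


def _genome_matches(tag_dna: str, genome: dict[str, str]
                    ) -> list[tuple[str, int, int, str]]:
    hits = []
    rc = reverse_complement(tag_dna)
    for contig, seq in genome.items():
        for query, strand in ((tag_dna, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append((contig, start, start + len(query), strand))
                start = seq.find(query, start + 1)
    return hits


def _excise(contig_seq: str, start: int, end: int, strand: str,
            up: int, down: int) -> tuple[str, int, int, int]:
    """Window around a mapped tag, in transcript orientation.

    Returns (precursor DNA in transcript orientation, genomic start,
    genomic end, mature offset within precursor).
    """
    if strand == "+":
        g_lo, g_hi = max(0, start - up), min(len(contig_seq), end + down)
        precursor = contig_seq[g_lo:g_hi]
        offset = start - g_lo
    else:
        g_lo, g_hi = max(0, start - down), min(len(contig_seq), end + up)
        precursor = reverse_complement(contig_seq[g_lo:g_hi])
        offset = g_hi - end
    return precursor, g_lo, g_hi, offset


def call_novel(tags: Iterable[TagCount], genome: dict[str, str],
               criteria: NovelCriteria | None = None,
               fold_backend: str = "builtin") -> list[HairpinCandidate]:
    """MIREAP-style hairpin calling for unannotated tags.

    Only tags with a perfect genomic match are considered; the mapped tag
    itself is the putative mature.  Both arm orientations are tried per
    locus and the first passing one is emitted; loci are deduplicated on
    (contig, mature position, strand).
    """
    criteria = criteria or NovelCriteria()
    candidates: list[HairpinCandidate] = []
    seen: set[tuple[str, int, int, str]] = set()
    for tc in tags:
        tag_dna = to_dna(tc.tag)
        for contig, start, end, strand in _genome_matches(tag_dna, genome):
            key = (contig, start, end, strand)
            if key in seen:
                continue
            if contig not in genome:
                raise KeyError(f"genome contig {contig!r} missing")
            best: HairpinCandidate | None = None
            for up, down in ((criteria.flank_up, criteria.flank_down),
                             (criteria.flank_down, criteria.flank_up)):
                precursor, g_lo, g_hi, offset = _excise(
                    genome[contig], start, end, strand, up, down)
                fr = fold(precursor, backend=fold_backend)
                flags, arm, star = evaluate_hairpin(fr, offset, len(tag_dna), criteria)
                cand = HairpinCandidate(
                    contig, g_lo, g_hi, strand, to_rna(precursor), fr,
                    to_rna(tag_dna), offset, arm, star, flags, tc.total,
                )
                if cand.passed:
                    best = cand
                    break
                if best is None:
                    best = cand
            if best is not None and best.passed:
                seen.add(key)
                candidates.append(best)
    return candidates


def nucleotide_bias(sequences: Sequence[str]) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Per-position base frequencies, 5'-U share, and length histogram.

    Positions are 1-based from the 5' end; each position's frequencies sum
    to 1 over the sequences long enough to reach it.  Percent shares in
    the length table are rounded half-up to 2 dp.
    """
    seqs = [to_rna(s) for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    max_len = max(len(s) for s in seqs)
    rows = []
    for pos in range(max_len):
        present = [s[pos] for s in seqs if len(s) > pos]
        n = len(present)
        rows.append({
            "position": pos + 1,
            **{base: present.count(base) / n for base in "ACGU"},
        })
    bias = pd.DataFrame(rows)
    first_u = sum(1 for s in seqs if s[0] == "U") / len(seqs)
    lengths = sorted({len(s) for s in seqs})
    length_df = pd.DataFrame({
        "length": lengths,
        "count": [sum(1 for s in seqs if len(s) == L) for L in lengths],
    })
    length_df["percent"] = [
        pct_half_up(c, len(seqs)) for c in length_df["count"]
    ]
    return bias, first_u, length_df
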