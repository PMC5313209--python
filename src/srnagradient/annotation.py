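"""Triage of clean unique tags against non-miRNA reference sets.

Tags are matched end-to-end (ungapped, bounded Hamming distance) against
an ordered list of reference collections — rRNA, tRNA, snRNA, snoRNA,
repeats, mRNA exons — and each tag takes the category of the first set it
hits.  What survives is "unannotated" and proceeds to miRNA calling.

No installed aligner exposes fixed-register Hamming matching as a
primitive (edlib computes full edit distance), so the sliding-window
matcher is implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqio import TagCount, reverse_complement, to_dna
from .utils import pct_half_up

CATEGORIES = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon_mRNA",
    "known_miRNA", "unannotated",
)

#: Default priority for the filtering sets (known_miRNA is a later stage).
DEFAULT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon_mRNA")

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclass
class ReferenceSet:
    """A labelled FASTA collection; U is converted to T on load."""

    label: str
    sequences: dict[str, str]
    both_strands: bool = False
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"reference set {self.label!r} is empty")
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown category {self.label!r}")
        self.sequences = {k: to_dna(v) for k, v in self.sequences.items()}


@dataclass(frozen=True)
class TagHit:
    reference_id: str
    position: int  # 0-based start on the reference (forward strand)
    strand: str
    mismatches: int


def hamming_within(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings if <= limit, else None."""
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return None
    return mismatches


def _scan(tag: str, ref_seq: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best (mismatches, leftmost position) of tag within one sequence."""
    best: tuple[int, int] | None = None
    for pos in range(len(ref_seq) - len(tag) + 1):
        d = hamming_within(tag, ref_seq[pos:pos + len(tag)], max_mismatch)
        if d is not None and (best is None or d < best[0]):
            best = (d, pos)
            if d == 0:
                break
    return best


def match_tag(tag: str, ref: ReferenceSet,
              max_mismatch: int | None = None) -> TagHit | None:
    """Best end-to-end ungapped hit of a tag in a reference set, or None.

    Both strands are searched only for sets flagged ``both_strands``
    (genome/transcriptome); structured ncRNA sets are strand-specific.
    Ties break by fewest mismatches, then reference file order, then
    leftmost position, with '+' preferred over '-'.
    """
    if not MIN_TAG_LEN <= len(tag) <= MAX_TAG_LEN:
        raise ValueError(f"tag length {len(tag)} outside [{MIN_TAG_LEN}, {MAX_TAG_LEN}]")
    limit = ref.max_mismatch if max_mismatch is None else max_mismatch
    tag = to_dna(tag)
    queries = [(tag, "+")]
    if ref.both_strands:
        queries.append((reverse_complement(tag), "-"))
    best: TagHit | None = None
    for ref_id, ref_seq in ref.sequences.items():
        for query, strand in queries:
            found = _scan(query, ref_seq, limit)
            if found is None:
                continue
            d, pos = found
            if best is None or d < best.mismatches:
                best = TagHit(ref_id, pos, strand, d)
    return best


def annotate_tags(tags: Sequence[TagCount], refs: Iterable[ReferenceSet]
                  ) -> tuple[dict[str, str], pd.DataFrame]:
    """Assign each tag the category of the first reference set it matches.

    Returns (tag -> category, summary table).  The summary reports
    unique-tag and total-read counts and shares per category; shares over
    unique tags partition to 100%.
    """
    refs = list(refs)
    categories: dict[str, str] = {}
    for tc in tags:
        category = "unannotated"
        for ref in refs:
            if match_tag(tc.tag, ref) is not None:
                category = ref.label
                break
        categories[tc.tag] = category
    return categories, summarize_annotation(tags, categories)


def summarize_annotation(tags: Sequence[TagCount],
                         categories: dict[str, str]) -> pd.DataFrame:
    order = [c for c in CATEGORIES if c != "known_miRNA"]
    unique = {c: 0 for c in order}
    reads = {c: 0 for c in order}
    for tc in tags:
        c = categories[tc.tag]
        unique[c] += 1
        reads[c] += tc.total
    n_unique = sum(unique.values())
    n_reads = sum(reads.values())
    return pd.DataFrame({
        "category": order,
        "unique_tags": [unique[c] for c in order],
        "unique_pct": [pct_half_up(unique[c], n_unique) for c in order],
        "total_reads": [reads[c] for c in order],
        "reads_pct": [pct_half_up(reads[c], n_reads) for c in order],
    })
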