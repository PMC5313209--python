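"""Readers/writers for the formats the pipeline touches, and tag collapsing.

FASTQ/FASTA parsing is delegated to Biopython; this module adds the thin
domain layer (RawRead / TagCount records, strict validation with line
numbers, deterministic tag collapsing) the rest of the pipeline relies on.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention happens only when GFF3 lines are emitted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FastqParseError(ValueError):
    """Raised for a structurally malformed FASTQ record; names the line."""


@dataclass(frozen=True)
class RawRead:
    """One sequencing read: id, uppercase DNA sequence, optional Phred string."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for read {self.read_id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for read {self.read_id!r}"
            )

    def mean_phred(self) -> float:
        if not self.quality:
            raise ValueError(f"read {self.read_id!r} has no quality string")
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)


@dataclass
class TagCount:
    """A unique small-RNA tag with its per-library read counts."""

    tag: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "N" in self.tag:
            raise ValueError(f"tag contains N: {self.tag}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative tag count")
        if self.counts and not any(c > 0 for c in self.counts.values()):
            raise ValueError("tag with all-zero counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fastq(path: str | os.PathLike) -> Iterator[RawRead]:
    """Stream RawReads from a 4-line-record FASTQ file (Sanger Phred+33).

    Sequences are uppercased.  Malformed records raise FastqParseError
    naming the (approximate) offending line.
    """
    n_records = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split(None, 1)[0]
                if len(qual) != len(seq):
                    raise FastqParseError(
                        f"{path}: near line {4 * n_records + 1}: quality length "
                        f"{len(qual)} != sequence length {len(seq)} for {read_id!r}"
                    )
                yield RawRead(read_id, seq.upper(), qual)
                n_records += 1
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(
                f"{path}: near line {4 * n_records + 1}: {exc}"
            ) from exc


def read_fasta(path: str | os.PathLike, *, rna_to_dna: bool = False) -> dict[str, str]:
    """Load a FASTA file into an ordered id -> uppercase-sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        records[rec.id] = to_dna(seq) if rna_to_dna else seq
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs as FASTA; ids must be unique."""
    seen: set[str] = set()
    with open(path, "w") as out:
        for rec_id, seq in records:
            if rec_id in seen:
                raise ValueError(f"duplicate FASTA id {rec_id!r}")
            seen.add(rec_id)
            out.write(f">{rec_id}\n{seq}\n")


def write_fastq(reads: Iterable[RawRead], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


@dataclass(frozen=True)
class GffFeature:
    """A genomic feature in internal 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    feature_type: str = "miRNA_primary_transcript"
    feature_id: str = ""
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Iterable[GffFeature], path: str | os.PathLike,
               source: str = "srnagradient") -> None:
    """Emit GFF3 (1-based inclusive coordinates, per the standard)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            if f.feature_id:
                attrs = {"ID": f.feature_id, **attrs}
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            score = "." if f.score is None else f"{f.score:g}"
            out.write(
                f"{f.contig}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}\t"
                f"{score}\t{f.strand}\t.\t{attr_str}\n"
            )


def write_tsv(table, path: str | os.PathLike) -> None:
    """Write a pandas DataFrame as a header-row TSV (no index column)."""
    table.to_csv(path, sep="\t", index=False)


def collapse_tags(reads_per_library: dict[str, Iterable]) -> list[TagCount]:
    """Collapse cleaned reads into unique tags with per-library counts.

    Accepts {library_id: iterable of sequences or objects with .insert /
    .sequence}.  Identity is exact forward-strand string equality; output
    order is lexicographic by tag, so it is deterministic.  Reads whose
    sequence contains N are not collapsible and raise.
    """
    counts: dict[str, dict[str, int]] = {}
    for lib, reads in reads_per_library.items():
        for read in reads:
            seq = getattr(read, "insert", None) or getattr(read, "sequence", None) or read
            per_tag = counts.setdefault(seq, {})
            per_tag[lib] = per_tag.get(lib, 0) + 1
    return [TagCount(tag, counts[tag]) for tag in sorted(counts)]
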