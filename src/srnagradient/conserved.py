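"""Conserved (known) miRNA identification, expression matrices, Venn algebra.

Tags that survive annotation triage are compared to a mature-miRNA
reference (a user-supplied FASTA snapshot, U or T alphabet) by 5'-anchored
ungapped alignment tolerating up to three substitutions and a +-2 nt 3'
length difference; only an identical-length, zero-mismatch tag is flagged
*conserved*.  Family counts are normalised to transcripts per million
clean reads (TPM), and per-site family sets are compared by exact
three-set Venn algebra.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cleaning import CleaningReport
from .seqio import TagCount, to_dna
from .utils import pct_half_up

#: Strips species prefix and allele/arm suffixes: mtr-miR398a-5p -> MIR398.
FAMILY_REGEX = r"^(?:[a-z]{3,4}[-_])?(?:miR|MIR)[-]?(\d+)"

MAX_MISMATCH = 3
LENGTH_TOLERANCE = 2


@dataclass(frozen=True)
class MirnaFamilyHit:
    tag: str
    reference_id: str
    family: str
    mismatches: int
    conserved_flag: bool

    def __post_init__(self) -> None:
        if self.mismatches > MAX_MISMATCH:
            raise ValueError("mismatches exceed the allowed maximum")
        if self.conserved_flag and self.mismatches != 0:
            raise ValueError("conserved hits must be perfect matches")


def parse_family(reference_id: str, pattern: str = FAMILY_REGEX) -> str:
    """Family label from a mature-miRNA id; falls back to the id itself."""
    match = re.match(pattern, reference_id)
    if match:
        return f"MIR{match.group(1)}"
    warnings.warn(f"cannot parse family from {reference_id!r}; using id as family")
    return reference_id


def _anchored_mismatches(tag: str, ref: str, limit: int) -> int | None:
    """Substitutions over the 5'-anchored overlap, or None if over limit."""
    mismatches = 0
    for a, b in zip(tag, ref):
        if a != b:
            mismatches += 1
            if mismatches > limit:
                return None
    return mismatches


def identify_known(tags: Iterable[TagCount], mature_ref: dict[str, str],
                   max_mismatch: int = MAX_MISMATCH,
                   family_pattern: str = FAMILY_REGEX) -> list[MirnaFamilyHit]:
    """Match tags to mature miRNAs; at most one (best) hit per tag.

    A hit requires the tag to be within +-2 nt of the reference length and
    to show <= ``max_mismatch`` substitutions in the 5'-anchored overlap.
    Ties break by fewest mismatches, then smallest length difference, then
    reference order.
    """
    ref_dna = {rid: to_dna(seq) for rid, seq in mature_ref.items()}
    hits: list[MirnaFamilyHit] = []
    for tc in tags:
        tag = to_dna(tc.tag)
        best: tuple[int, int, int, str] | None = None  # (mm, |dlen|, order, id)
        for order, (rid, ref) in enumerate(ref_dna.items()):
            dlen = len(tag) - len(ref)
            if abs(dlen) > LENGTH_TOLERANCE:
                continue
            mm = _anchored_mismatches(tag, ref, max_mismatch)
            if mm is None:
                continue
            key = (mm, abs(dlen), order, rid)
            if best is None or key < best:
                best = key
        if best is not None:
            mm, _, _, rid = best
            conserved = mm == 0 and len(tag) == len(ref_dna[rid])
            hits.append(MirnaFamilyHit(tc.tag, rid,
                                       parse_family(rid, family_pattern),
                                       mm, conserved))
    return hits


@dataclass
class ExpressionMatrix:
    """Family x library count matrix plus its TPM normalisation."""

    counts: pd.DataFrame
    tpm: pd.DataFrame

    def family(self, name: str) -> pd.Series:
        return self.tpm.loc[name]


def build_expression(hits_per_library: dict[str, Sequence[tuple[MirnaFamilyHit, int]]],
                     report: CleaningReport) -> ExpressionMatrix:
    """Aggregate (hit, tag count) pairs into family counts and TPM.

    TPM = count * 1e6 / clean_reads of the library; a library with zero
    clean reads cannot be normalised and is an error.
    """
    libraries = list(hits_per_library)
    families = sorted({h.family for hits in hits_per_library.values() for h, _ in hits})
    counts = pd.DataFrame(0, index=families, columns=libraries, dtype=int)
    for lib, hits in hits_per_library.items():
        for hit, n in hits:
            counts.loc[hit.family, lib] += n
    tpm = counts.astype(float).copy()
    for lib in libraries:
        clean = report.clean_reads(lib)
        if clean <= 0:
            raise ValueError(f"library {lib!r} has no clean reads")
        tpm[lib] = counts[lib] * 1e6 / clean
    return ExpressionMatrix(counts, tpm)


@dataclass
class VennSummary:
    """Disjoint-region counts of a three-set comparison.

    ``only_*`` are exclusive regions; ``ab``/``bc``/``ac`` are exclusive
    pairwise regions (triple NOT included); ``abc`` is the triple overlap.
    """

    labels: tuple[str, str, str]
    only_a: int
    only_b: int
    only_c: int
    ab: int
    bc: int
    ac: int
    abc: int

    def __post_init__(self) -> None:
        if min(self.only_a, self.only_b, self.only_c,
               self.ab, self.bc, self.ac, self.abc) < 0:
            raise ValueError("negative Venn region")

    @property
    def union(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.ab + self.bc + self.ac + self.abc)

    @property
    def totals(self) -> dict[str, int]:
        a, b, c = self.labels
        return {
            a: self.only_a + self.ab + self.ac + self.abc,
            b: self.only_b + self.ab + self.bc + self.abc,
            c: self.only_c + self.ac + self.bc + self.abc,
        }

    def shared_pairwise(self) -> dict[str, int]:
        """Pairwise overlaps as usually quoted (triple region included)."""
        a, b, c = self.labels
        return {
            f"{a}-{b}": self.ab + self.abc,
            f"{b}-{c}": self.bc + self.abc,
            f"{a}-{c}": self.ac + self.abc,
        }

    def percent_of_union(self, region_count: int) -> float:
        return pct_half_up(region_count, self.union)

    @classmethod
    def from_shared_counts(cls, labels: tuple[str, str, str],
                           unique: tuple[int, int, int],
                           shared: tuple[int, int, int],
                           triple: int) -> "VennSummary":
        """Build from quoted numbers: uniques, pairwise *including* triple
        (AB, BC, AC order), and the triple overlap."""
        ab, bc, ac = (s - triple for s in shared)
        return cls(labels, *unique, ab, bc, ac, triple)

    def to_dataframe(self) -> pd.DataFrame:
        a, b, c = self.labels
        rows = [
            (f"{a} only", self.only_a), (f"{b} only", self.only_b),
            (f"{c} only", self.only_c),
            (f"{a}&{b} only", self.ab), (f"{b}&{c} only", self.bc),
            (f"{a}&{c} only", self.ac), ("all three", self.abc),
            ("union", self.union),
        ]
        df = pd.DataFrame(rows, columns=["region", "count"])
        df["pct_of_union"] = [self.percent_of_union(n) for _, n in rows]
        return df


def venn(sets: dict[str, set[str] | Sequence[str]]) -> VennSummary:
    """Exact three-set Venn region counts from family-id collections."""
    if len(sets) != 3:
        raise ValueError("exactly three sets required")
    labels = tuple(sets)
    a, b, c = (set(sets[k]) for k in labels)
    return VennSummary(
        labels,
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab=len((a & b) - c),
        bc=len((b & c) - a),
        ac=len((a & c) - b),
        abc=len(a & b & c),
    )
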