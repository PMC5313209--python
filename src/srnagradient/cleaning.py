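"""Read-filtering cascade for raw small-RNA libraries.

Raw reads are first screened for base quality, then classified by a fixed
cascade of removal categories (3' adapter missing, empty insert, 5' adapter
carry-over, <18 nt insert, poly-A) mirroring the bookkeeping a sequencing
report prints: every high-quality read lands in exactly one terminal bin,
and the clean-read count is what survives all removals.

The first matching test wins, so the report is well defined even when a
read would satisfy several removal criteria.  Inserts longer than the
30-nt analysis window are retained as clean here and excluded later at the
mapping stage (the report has no "too long" category).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqio import RawRead
from .utils import pct_half_up

#: Terminal removal categories, in cascade (and report-row) order.
REMOVAL_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminants",
    "smaller_than_18nt",
    "polyA",
)

REPORT_ROWS = ("total_reads", "high_quality") + (
    "3'adapter_null",
    "insert_null",
    "5'adapter_contaminants",
    "smaller_than_18nt",
    "polyA",
    "clean_reads",
)


@dataclass
class CleaningConfig:
    """Thresholds for the filtering cascade.

    min/max_insert_len bound the analysis window (18-30 nt); polya_fraction
    is the minimum A share for the poly-A bin; adapter matching requires at
    least ``adapter_min_overlap`` aligned bases at no more than
    ``adapter_max_mismatch_rate`` mismatches.
    """

    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_insert_len: int = 18
    max_insert_len: int = 30
    polya_fraction: float = 0.8
    min_mean_quality: float = 20.0
    max_n_bases: int = 0
    adapter_min_overlap: int = 6
    adapter_max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.min_insert_len > self.max_insert_len:
            raise ValueError("min_insert_len > max_insert_len")
        if not 0 < self.polya_fraction <= 1:
            raise ValueError("polya_fraction must be in (0, 1]")
        if not 0 <= self.adapter_max_mismatch_rate < 1:
            raise ValueError("adapter_max_mismatch_rate must be in [0, 1)")
        self.adapter3 = self.adapter3.upper()
        self.adapter5 = self.adapter5.upper()


@dataclass(frozen=True)
class CleanRead:
    read_id: str
    insert: str
    library: str = ""


@dataclass
class CleaningReport:
    """Per-library removal bookkeeping (one column per library)."""

    libraries: list[str] = field(default_factory=list)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add_library(self, library: str, total_reads: int, high_quality: int,
                    removed: dict[str, int], clean_reads: int) -> None:
        expected = clean_reads + sum(removed.get(c, 0) for c in REMOVAL_CATEGORIES)
        if expected != high_quality:
            raise ValueError(
                f"{library}: categories sum to {expected}, high_quality is {high_quality}"
            )
        if high_quality > total_reads:
            raise ValueError(f"{library}: high_quality exceeds total_reads")
        self.libraries.append(library)
        self.counts[library] = {
            "total_reads": total_reads,
            "high_quality": high_quality,
            **{c: removed.get(c, 0) for c in REMOVAL_CATEGORIES},
            "clean_reads": clean_reads,
        }

    def clean_reads(self, library: str) -> int:
        return self.counts[library]["clean_reads"]

    def percent(self, library: str, category: str) -> float:
        """Share of high-quality reads, 2 dp; high_quality itself prints 100%."""
        hq = self.counts[library]["high_quality"]
        if category == "total_reads":
            raise ValueError("total_reads has no percentage")
        return pct_half_up(self.counts[library][category], hq)

    def to_dataframe(self) -> pd.DataFrame:
        """Table with interleaved count / percent columns per library."""
        display = {
            "adapter3_null": "3'adapter_null",
            "adapter5_contaminants": "5'adapter_contaminants",
        }
        rows = ["total_reads", "high_quality", *REMOVAL_CATEGORIES, "clean_reads"]
        data: dict[str, list] = {"category": [display.get(r, r) for r in rows]}
        for lib in self.libraries:
            data[f"{lib}_count"] = [self.counts[lib][r] for r in rows]
            data[f"{lib}_percent"] = [
                "" if r == "total_reads" else f"{self.percent(lib, r):.2f}%"
                for r in rows
            ]
        return pd.DataFrame(data)


def derive_clean_reads(high_quality: int, removed: Sequence[int]) -> tuple[int, float]:
    """Clean-read count and its percentage of high-quality, from removal counts.

    This is the conservation identity of the report: clean = high_quality
    minus the five removal bins.
    """
    clean = high_quality - sum(removed)
    if clean < 0:
        raise ValueError("removal categories exceed high_quality")
    return clean, pct_half_up(clean, high_quality)


def quality_filter(read: RawRead, cfg: CleaningConfig) -> bool:
    """True iff the read passes mean-Phred and N-count screens."""
    if read.sequence.count("N") > cfg.max_n_bases:
        return False
    if cfg.min_mean_quality is not None:
        if read.quality is None:
            raise ValueError(f"read {read.read_id!r} lacks quality string")
        if read.mean_phred() < cfg.min_mean_quality:
            return False
    return True


def find_adapter(sequence: str, adapter: str, min_overlap: int,
                 max_mismatch_rate: float) -> int | None:
    """Leftmost start of a 3' adapter occurrence, or None.

    The adapter may run off the read's 3' end; an occurrence needs at least
    ``min_overlap`` aligned bases with a mismatch rate <= ``max_mismatch_rate``.
    """
    n = len(sequence)
    last_start = n - min_overlap
    for p in range(0, last_start + 1):
        k = min(len(adapter), n - p)
        limit = int(max_mismatch_rate * k)
        mismatches = 0
        for a, b in zip(adapter[:k], sequence[p:p + k]):
            if a != b:
                mismatches += 1
                if mismatches > limit:
                    break
        else:
            return p
    return None


def classify_and_trim(read: RawRead, cfg: CleaningConfig
                      ) -> tuple[str, CleanRead | None]:
    """Assign a quality-passed read to its single cascade category.

    Order is fixed: adapter3_null, insert_null, adapter5_contaminants,
    smaller_than_18nt, polyA, clean.
    """
    pos = find_adapter(read.sequence, cfg.adapter3,
                       cfg.adapter_min_overlap, cfg.adapter_max_mismatch_rate)
    if pos is None:
        return "adapter3_null", None
    if pos == 0:
        return "insert_null", None
    insert = read.sequence[:pos]
    if cfg.adapter5 and cfg.adapter5 in insert:
        return "adapter5_contaminants", None
    if len(insert) < cfg.min_insert_len:
        return "smaller_than_18nt", None
    if insert.count("A") / len(insert) >= cfg.polya_fraction:
        return "polyA", None
    return "clean", CleanRead(read.read_id, insert)


def clean_library(reads: Iterable[RawRead], cfg: CleaningConfig,
                  library: str = "lib") -> tuple[list[CleanRead], CleaningReport]:
    """Run the full cascade over one library and tally the report."""
    total = 0
    high_quality = 0
    removed = {c: 0 for c in REMOVAL_CATEGORIES}
    clean: list[CleanRead] = []
    for read in reads:
        total += 1
        if not quality_filter(read, cfg):
            continue
        high_quality += 1
        category, clean_read = classify_and_trim(read, cfg)
        if category == "clean":
            clean.append(CleanRead(clean_read.read_id, clean_read.insert, library))
        else:
            removed[category] += 1
    report = CleaningReport()
    report.add_library(library, total, high_quality, removed, len(clean))
    return clean, report


def merge_reports(reports: Iterable[CleaningReport]) -> CleaningReport:
    merged = CleaningReport()
    for rep in reports:
        for lib in rep.libraries:
            c = rep.counts[lib]
            merged.add_library(
                lib, c["total_reads"], c["high_quality"],
                {k: c[k] for k in REMOVAL_CATEGORIES}, c["clean_reads"],
            )
    return merged
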