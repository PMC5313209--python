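import numpy as np
import pytest

from srnagradient.annotation import ReferenceSet, annotate_tags, match_tag
from srnagradient.seqio import TagCount, reverse_complement


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_exact_substring_hit():
    ref = ReferenceSet("rRNA", {"r1": "G" * 10 + "ACGTACGTACGTACGTACGTA" + "C" * 10})
    hit = match_tag("ACGTACGTACGTACGTACGTA", ref)
    assert hit is not None and hit.mismatches == 0 and hit.position == 10


def test_reverse_complement_hit_on_minus_strand():
    core = "ATGGCGTTAGCCTTAGGCATG"
    ref = ReferenceSet("exon_mRNA", {"t1": "T" * 8 + core + "G" * 8},
                       both_strands=True)
    hit = match_tag(reverse_complement(core), ref)
    assert hit is not None and hit.strand == "-"


def test_tag_length_window_enforced():
    ref = ReferenceSet("rRNA", {"r1": "ACGT" * 20})
    with pytest.raises(ValueError):
        match_tag("ACGT", ref)


def test_match_tag_equals_bruteforce_hamming_oracle():
    """Sliding-window matcher agrees with a naive Hamming scan on random data."""
    rng = np.random.default_rng(7)
    ref_seqs = {f"r{i}": _rand_seq(rng, 60) for i in range(5)}
    ref = ReferenceSet("repeat", ref_seqs, max_mismatch=2)
    for _ in range(500):
        tag = _rand_seq(rng, int(rng.integers(18, 25)))
        got = match_tag(tag, ref)
        # oracle: enumerate every window of every reference
        best = None
        for rid, seq in ref_seqs.items():
            for pos in range(len(seq) - len(tag) + 1):
                d = sum(a != b for a, b in zip(tag, seq[pos:pos + len(tag)]))
                if d <= 2 and (best is None or d < best[0]):
                    best = (d, rid, pos)
        if best is None:
            assert got is None
        else:
            assert got is not None
            assert got.mismatches == best[0]


def _tagset(seqs):
    return [TagCount(s, {"lib": 1}) for s in seqs]


def test_priority_first_match_wins():
    seq = "ACGTACGTACGTACGTACGTA"
    rrna = ReferenceSet("rRNA", {"r": "TT" + seq + "GG"})
    repeat = ReferenceSet("repeat", {"p": seq})
    categories, _ = annotate_tags(_tagset([seq]), [rrna, repeat])
    assert categories[seq] == "rRNA"


def test_unmatched_tag_is_unannotated_and_partition_sums():
    rng = np.random.default_rng(11)
    tags = _tagset([_rand_seq(rng, 20) for _ in range(20)])
    ref = ReferenceSet("rRNA", {"r": _rand_seq(rng, 100)})
    categories, summary = annotate_tags(tags, [ref])
    assert set(categories.values()) <= {"rRNA", "unannotated"}
    assert summary["unique_tags"].sum() == len(tags)
    assert abs(summary["unique_pct"].sum() - 100.0) < 0.05


def test_priority_monotonicity():
    """Adding a lower-priority set never changes an annotated tag's class."""
    rng = np.random.default_rng(13)
    ref_a = ReferenceSet("rRNA", {"r": _rand_seq(rng, 120)})
    ref_b = ReferenceSet("tRNA", {"t": _rand_seq(rng, 120)})
    tags = _tagset(
        [ref_a.sequences["r"][i:i + 20] for i in range(0, 60, 7)]
        + [_rand_seq(rng, 20) for _ in range(10)]
    )
    before, _ = annotate_tags(tags, [ref_a])
    after, _ = annotate_tags(tags, [ref_a, ref_b])
    for tag, cat in before.items():
        if cat != "unannotated":
            assert after[tag] == cat


def test_planted_fragments_recovered_by_class(sim_run, pipeline_report):
    """Reads planted from each ncRNA class must annotate back to it."""
    summary = pipeline_report.annotation_summary.set_index("category")
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon_mRNA"):
        assert summary.loc[cls, "unique_tags"] > 0, cls
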