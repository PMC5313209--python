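import pytest

from srnagradient.cleaning import (CleaningConfig, CleaningReport, REMOVAL_CATEGORIES,
                                   classify_and_trim, clean_library,
                                   derive_clean_reads, quality_filter)
from srnagradient.seqio import RawRead

CFG = CleaningConfig()
AD3 = CFG.adapter3
AD5 = CFG.adapter5


def read(seq, qual=None):
    return RawRead("r", seq, qual if qual is not None else "I" * len(seq))


def test_quality_filter_pass_and_fail():
    assert quality_filter(read("ACGT" * 10), CFG)
    assert not quality_filter(read("ACGT" * 10, "#" * 40), CFG)  # mean Q2
    assert not quality_filter(read("ACGN" + "ACGT" * 9), CFG)    # N with max 0


def test_classify_insert_null():
    cat, _ = classify_and_trim(read(AD3 + "ACGTACGT"), CFG)
    assert cat == "insert_null"


def test_classify_adapter3_null():
    cat, _ = classify_and_trim(read("ACGTGTCA" * 6), CFG)
    assert cat == "adapter3_null"


def test_classify_polya():
    cat, _ = classify_and_trim(read("A" * 20 + AD3), CFG)
    assert cat == "polyA"


def test_classify_adapter5_contaminant_before_length():
    cat, _ = classify_and_trim(read(AD5 + "ACGT" + AD3), CFG)
    assert cat == "adapter5_contaminants"


def test_classify_short_insert():
    cat, _ = classify_and_trim(read("GCGTACGTTGCGT" + AD3), CFG)
    assert cat == "smaller_than_18nt"


def test_classify_clean_trims_adapter():
    insert = "GCTAGCTAGGATCGATCGAT"
    cat, clean = classify_and_trim(read(insert + AD3), CFG)
    assert cat == "clean"
    assert clean.insert == insert


def test_table_bookkeeping_first_column():
    """Published removal counts must reproduce the printed clean-read total."""
    clean, pct = derive_clean_reads(
        13_705_945, [23_996, 16_067, 7_754, 34_563, 3_318])
    assert clean == 13_620_247
    assert pct == 99.37


@pytest.mark.parametrize("high_quality, removed, expected_clean, expected_pct", [
    (15_043_247, [27_573, 14_945, 7_642, 34_190, 4_505], 14_954_392, 99.41),
    (15_192_717, [22_424, 20_034, 8_250, 36_983, 2_784], 15_102_242, 99.40),
])
def test_table_bookkeeping_other_columns(high_quality, removed,
                                         expected_clean, expected_pct):
    clean, pct = derive_clean_reads(high_quality, removed)
    assert clean == expected_clean
    assert pct == expected_pct


def test_empty_input_all_zero_report():
    clean, report = clean_library([], CFG, "lib")
    assert clean == []
    assert all(v == 0 for v in report.counts["lib"].values())


def test_report_conservation_enforced():
    report = CleaningReport()
    with pytest.raises(ValueError):
        report.add_library("x", 100, 90, {c: 10 for c in REMOVAL_CATEGORIES}, 90)


def test_planted_category_counts_recovered_exactly(sim_run, pipeline_report):
    """On simulated libraries every read must land in its planted bin."""
    for lib in sim_run.truth["libraries"]:
        truth = sim_run.truth["cleaning"][lib]
        got = pipeline_report.cleaning.counts[lib]
        assert got["total_reads"] == truth["total_reads"]
        assert got["high_quality"] == truth["high_quality"]
        for cat, n in truth["categories"].items():
            key = "clean_reads" if cat == "clean" else cat
            assert got[key] == n, (lib, cat)


def test_report_percentages_recomputable(pipeline_report):
    rep = pipeline_report.cleaning
    for lib in rep.libraries:
        hq = rep.counts[lib]["high_quality"]
        assert rep.percent(lib, "high_quality") == 100.0
        recomputed = round(rep.counts[lib]["clean_reads"] / hq * 100, 2)
        assert abs(rep.percent(lib, "clean_reads") - recomputed) <= 0.01
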