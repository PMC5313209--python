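import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srnagradient.cleaning import CleaningReport
from srnagradient.conserved import (MirnaFamilyHit, VennSummary, build_expression,
                                    identify_known, parse_family, venn)
from srnagradient.seqio import TagCount


def _tags(seqs):
    return [TagCount(s, {"lib": 1}) for s in seqs]


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


REF = {"mtr-miR398a-5p": "TGTGTTCTCAGGTCACCCCTT",
       "ath-miR390a": "AAGCTCAGGAGGGATAGCGCC"}


def test_identical_tag_is_conserved():
    hits = identify_known(_tags([REF["mtr-miR398a-5p"]]), REF)
    assert len(hits) == 1
    h = hits[0]
    assert h.mismatches == 0 and h.conserved_flag and h.family == "MIR398"


def test_three_mismatches_hit_but_not_conserved():
    tag = "ATTGTTCTCAGGTCACCCCTA"  # 3 substitutions from miR398a
    hits = identify_known(_tags([tag]), REF)
    assert len(hits) == 1
    assert hits[0].mismatches == 3 and not hits[0].conserved_flag


def test_four_mismatches_is_no_hit():
    tag = "ATTGATCTCAGGTCACCCCTA"  # 4 substitutions
    assert identify_known(_tags([tag]), REF) == []


def test_length_tolerance_isomir():
    tag = REF["ath-miR390a"][:-2]  # 3'-trimmed by 2 nt
    hits = identify_known(_tags([tag]), REF)
    assert len(hits) == 1
    assert hits[0].mismatches == 0 and not hits[0].conserved_flag


def test_identify_known_equals_bruteforce_oracle():
    rng = np.random.default_rng(3)
    refs = {f"osa-miR{100 + i}": _rand_seq(rng, int(rng.integers(20, 23)))
            for i in range(50)}
    tags = [_rand_seq(rng, int(rng.integers(18, 25))) for _ in range(60)]
    # plant some near-misses
    for i, rid in enumerate(list(refs)[:10]):
        s = list(refs[rid])
        for p in range(i % 4):
            s[p] = "A" if s[p] != "A" else "C"
        tags.append("".join(s))
    hits = {h.tag for h in identify_known(_tags(tags), refs)}
    oracle = set()
    for tag in tags:
        for ref in refs.values():
            if abs(len(tag) - len(ref)) > 2:
                continue
            if sum(a != b for a, b in zip(tag, ref)) <= 3:
                oracle.add(tag)
                break
    assert hits == oracle


def test_family_parsing_variants():
    assert parse_family("mtr-miR398a-5p") == "MIR398"
    assert parse_family("ath-miR166b-3p") == "MIR166"
    assert parse_family("MIR2119") == "MIR2119"
    with pytest.warns(UserWarning):
        assert parse_family("weird_id_7") == "weird_id_7"


def _report(clean: dict[str, int]) -> CleaningReport:
    rep = CleaningReport()
    for lib, n in clean.items():
        rep.add_library(lib, n, n, {}, n)
    return rep


def test_tpm_closed_forms():
    hit = MirnaFamilyHit("T" * 21, "ath-miR390a", "MIR390", 0, True)
    matrix = build_expression({"A": [(hit, 1000)], "B": []},
                              _report({"A": 1000, "B": 500}))
    assert matrix.tpm.loc["MIR390", "A"] == 1_000_000
    assert matrix.tpm.loc["MIR390", "B"] == 0
    assert matrix.counts.loc["MIR390", "B"] == 0


def test_tpm_zero_clean_reads_is_error():
    hit = MirnaFamilyHit("T" * 21, "x-miR1", "MIR1", 0, True)
    with pytest.raises(ValueError):
        build_expression({"A": [(hit, 1)]}, _report({"A": 0}))


def test_published_venn_regions_reproduce_totals():
    """The quoted region counts must give union 490 and the site totals."""
    vs = VennSummary.from_shared_counts(
        ("HuL", "YuL", "DaB"), unique=(84, 87, 62),
        shared=(199, 206, 206), triple=177)
    assert vs.union == 490
    assert vs.totals["HuL"] == 312
    assert vs.percent_of_union(vs.abc) == 36.12
    assert vs.percent_of_union(84) == 17.14
    assert vs.percent_of_union(87) == 17.76
    assert vs.shared_pairwise() == {"HuL-YuL": 199, "YuL-DaB": 206, "HuL-DaB": 206}


def test_novel_triple_share():
    from srnagradient.utils import pct_half_up
    assert pct_half_up(19, 96) == 19.79


def test_venn_identical_sets():
    ids = {f"MIR{i}" for i in range(12)}
    vs = venn({"a": ids, "b": ids, "c": ids})
    assert vs.abc == 12 and vs.union == 12
    assert vs.only_a == vs.ab == vs.bc == vs.ac == 0


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from([f"m{i}" for i in range(30)]), max_size=30),
       st.lists(st.sampled_from([f"m{i}" for i in range(30)]), max_size=30),
       st.lists(st.sampled_from([f"m{i}" for i in range(30)]), max_size=30))
def test_venn_inclusion_exclusion(a, b, c):
    sa, sb, sc = set(a), set(b), set(c)
    vs = venn({"a": sa, "b": sb, "c": sc})
    assert vs.union == len(sa | sb | sc)
    incl_excl = (len(sa) + len(sb) + len(sc) - len(sa & sb) - len(sb & sc)
                 - len(sa & sc) + len(sa & sb & sc))
    assert vs.union == incl_excl
    assert vs.totals == {"a": len(sa), "b": len(sb), "c": len(sc)}


def test_tpm_recovers_planted_abundances(sim_run, pipeline_report):
    tpm = pipeline_report.expression.tpm
    truth = sim_run.truth
    for mid, info in truth["known_mirnas"].items():
        fam = info["family"]
        for lib, count in info["counts"].items():
            clean = pipeline_report.cleaning.clean_reads(lib)
            expected = count * 1e6 / clean
            assert tpm.loc[fam, lib] == pytest.approx(expected, rel=1e-9)
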